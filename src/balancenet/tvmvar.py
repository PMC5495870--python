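"""Multi-trial time-variant MVAR estimation by linear Kalman filtering.

Model
-----
The channel vector x(t) ∈ R^D follows a time-varying VAR(p),

    x(t) = Σ_{k=1..p} A_k(t) x(t−k) + e(t),      e(t) ~ N(0, Σ(t)),

whose coefficients evolve as a random walk.  The vectorized coefficients
form the Kalman state; with diagonal measurement noise the state
factorizes into D independent blocks (one per target channel, dimension
p·D), which is how the filter is implemented.  Per channel i:

    state      a_i(t) = a_i(t−1) + w(t),     w ~ N(0, c2²·I)
    observation x_i(t) = z(t)ᵀ a_i(t) + e_i(t),

with z(t) the stacked p previous samples of all channels.  The
measurement-noise variance r_i is adapted online by exponential
smoothing of the squared innovations with rate c1 (this is the
"adaptation of the covariance matrix" control constant; c2 is the
random-walk step width).  Multiple trials update the same state
sequentially at each time step before the filter advances, so trial
information is fused without averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import MultiTrialRecording
from .timefreq import TimeFrequencyMap

__all__ = [
    "KalmanConfig",
    "TimeVaryingVAR",
    "TvMVARResults",
    "select_order",
    "grand_mean_model",
]


@dataclass(frozen=True)
class KalmanConfig:
    """Kalman filter control parameters.

    ``c1`` — adaptation rate of the measurement-noise (innovation)
    variance; ``c2`` — step width (standard deviation, so the process
    variance is c2²) of the coefficient random walk; ``p`` — model order
    (20 at 100 Hz in the balancing study).
    """

    c1: float = 0.02
    c2: float = 0.005
    p: int = 20
    init_coeffs: float = 0.0
    init_state_cov: float = 1.0

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("c1 and c2 must be positive")
        if self.p < 1:
            raise ValueError("model order must be >= 1")


class TimeVaryingVAR:
    """Time-variant VAR model for multi-trial epoched recordings.

    Parameters
    ----------
    epochs
        Epoched recording; all trials of all subjects are fused into one
        coefficient trajectory (fit per subject by slicing beforehand).
    order
        AR model order p.
    c1, c2
        Kalman control parameters (innovation-variance adaptation rate
        and random-walk step width).

    Examples
    --------
    >>> model = TimeVaryingVAR(epochs, order=20, c1=0.02, c2=0.005)
    >>> res = model.fit()
    >>> res.A.shape        # (n_samples, p, D, D)
    >>> pdc = res.gpdc(freqs=np.arange(1, 31, 0.5))
    """

    def __init__(
        self,
        epochs: MultiTrialRecording,
        order: int = 20,
        c1: float = 0.02,
        c2: float = 0.005,
        config: KalmanConfig | None = None,
        exclude_channels: tuple[str, ...] = ("EOG",),
    ) -> None:
        self.config = config or KalmanConfig(c1=c1, c2=c2, p=order)
        keep = [i for i, c in enumerate(epochs.channel_names) if c not in exclude_channels]
        self.channel_names = [epochs.channel_names[i] for i in keep]
        # collapse subjects × trials into one trial axis
        data = epochs.data[:, :, keep, :]
        S, R, D, T = data.shape
        self.data = data.reshape(S * R, D, T)
        self.fs = epochs.fs
        if self.config.p >= T:
            raise ValueError("model order must be smaller than the number of samples")
        if S * R < 1:
            raise ValueError("need at least one trial")

    def fit(self) -> "TvMVARResults":
        """Run the multi-trial Kalman filter; returns the full trajectory."""
        cfg = self.config
        R, D, T = self.data.shape
        p = cfg.p
        m = p * D

        a = np.full((D, m), cfg.init_coeffs, float)
        P = np.repeat(np.eye(m)[None] * cfg.init_state_cov, D, axis=0)  # (D, m, m)
        r = np.maximum(self.data.var(axis=(0, 2)), 1e-12)  # per-channel meas. noise
        q = cfg.c2**2  # c2 is the random-walk step width (an SD)

        A = np.empty((T, p, D, D))
        sigma2 = np.empty((T, D))
        A[:p] = cfg.init_coeffs
        sigma2[:p] = r

        diag = np.arange(m)
        for t in range(p, T):
            # prediction: random-walk state, inflate covariance
            P[:, diag, diag] += q
            # regressor: p most recent samples, newest first, all channels
            Z = self.data[:, :, t - p : t][:, :, ::-1]  # (R, D, p)
            Z = Z.transpose(0, 2, 1).reshape(R, m)  # lag-major to match A layout
            for trial in range(R):
                z = Z[trial]
                y = self.data[trial, :, t]  # (D,)
                Pz = P @ z  # (D, m)
                s = Pz @ z + r  # (D,)
                if np.any(s <= 0) or not np.all(np.isfinite(s)):
                    warnings.warn("singular innovation covariance; ridge-stabilized")
                    P[:, diag, diag] += 1e-8
                    Pz = P @ z
                    s = Pz @ z + r
                nu = y - a @ z  # innovations (D,)
                gain = Pz / s[:, None]
                a += gain * nu[:, None]
                P -= gain[:, :, None] * Pz[:, None, :]
                r = (1.0 - cfg.c1) * r + cfg.c1 * nu**2
            A[t] = a.reshape(D, p, D).transpose(1, 0, 2)  # (p, D, D): A[k, i, j]
            sigma2[t] = r
        return TvMVARResults(self, A, sigma2)


class TvMVARResults:
    """Fitted time-variant VAR: coefficient trajectory and diagnostics.

    Attributes
    ----------
    A : ndarray, shape (n_samples, p, D, D)
        ``A[t, k−1, i, j]`` is the influence of channel j at lag k on
        channel i at time t.
    sigma2 : ndarray, shape (n_samples, D)
        Adapted residual (innovation) variances per channel.
    """

    def __init__(self, model: TimeVaryingVAR, A: np.ndarray, sigma2: np.ndarray) -> None:
        self.model = model
        self.A = A
        self.sigma2 = sigma2
        self.fs = model.fs
        self.p = model.config.p
        self.channel_names = model.channel_names

    @property
    def n_samples(self) -> int:
        return self.A.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    @property
    def D(self) -> int:
        return self.A.shape[-1]

    # -- diagnostics -------------------------------------------------------
    def companion_spectral_radius(self, t_step: int = 10, burn_in: float = 1.0) -> np.ndarray:
        """Spectral radius of the companion matrix on a time subgrid.

        The first ``burn_in`` seconds (filter convergence) are skipped.
        """
        from .synthdata import companion_spectral_radius

        start = max(self.p, int(round(burn_in * self.fs)))
        idx = np.arange(start, self.n_samples, t_step)
        return np.array([companion_spectral_radius(self.A[t]) for t in idx])

    def is_stable(self, t_step: int = 10, burn_in: float = 1.0) -> bool:
        """True when the fitted model stays stationary (ρ < 1) past burn-in."""
        return bool(np.all(self.companion_spectral_radius(t_step, burn_in) < 1.0))

    def time_average(self, t_lo: float | None = None, t_hi: float | None = None) -> np.ndarray:
        """Time-averaged coefficient stack (p, D, D) over [t_lo, t_hi)."""
        t = self.times
        lo = self.p / self.fs if t_lo is None else t_lo
        hi = t[-1] + 1 / self.fs if t_hi is None else t_hi
        sel = (t >= lo) & (t < hi)
        return self.A[sel].mean(axis=0)

    # -- frequency-domain products ----------------------------------------
    def transfer_polynomial(self, freqs: np.ndarray, t_step: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Ā(f, t) = I − Σ_k A_k(t) e^{−i2πfk/fs} on a time subgrid.

        Returns ``(Abar, t_index)`` with ``Abar`` of shape
        (n_t, n_f, D, D).
        """
        freqs = np.asarray(freqs, float)
        if np.any(freqs <= 0) or np.any(freqs >= self.fs / 2):
            raise ValueError("frequencies must lie in (0, fs/2)")
        t_index = np.arange(0, self.n_samples, t_step)
        k = np.arange(1, self.p + 1)
        E = np.exp(-2j * np.pi * np.outer(freqs, k) / self.fs)  # (F, p)
        Asub = self.A[t_index]  # (nt, p, D, D)
        Abar = -np.einsum("fk,tkij->tfij", E, Asub)
        Abar += np.eye(self.D)
        return Abar, t_index

    def amplitude_tfm(
        self, freqs: np.ndarray | None = None, t_step: int = 1
    ) -> list[TimeFrequencyMap]:
        """Parametric amplitude time–frequency map per channel.

        The spectral matrix is S(f, t) = H Σ H* with H = Ā⁻¹ and
        Σ = diag(σ²); the map holds √S_ii, an (unnormalized) amplitude
        spectral density in µV units.  Tiles where Ā is numerically
        singular are set to NaN.
        """
        if freqs is None:
            freqs = np.arange(0.5, self.fs / 2, 0.5)
        Abar, t_index = self.transfer_polynomial(freqs, t_step)
        nt, nf, D, _ = Abar.shape
        amp = np.empty((nt, nf, D))
        sig = self.sigma2[t_index]  # (nt, D)
        for ti in range(nt):
            try:
                H = np.linalg.inv(Abar[ti])  # (nf, D, D)
            except np.linalg.LinAlgError:
                warnings.warn(f"singular transfer polynomial at t index {ti}")
                amp[ti] = np.nan
                continue
            S = np.einsum("fij,j,fkj->fik", H, sig[ti], H.conj())
            amp[ti] = np.sqrt(np.abs(np.einsum("fii->fi", S)))
        times = t_index / self.fs
        return [
            TimeFrequencyMap(amp[:, :, c], times, freqs, "amplitude", self.channel_names[c])
            for c in range(D)
        ]

    def gpdc(self, freqs: np.ndarray | None = None, t_step: int = 1):
        """Time-variant generalized partial directed coherence tensor."""
        from .connectivity import gpdc

        return gpdc(self, freqs=freqs, t_step=t_step)

    def summary(self) -> str:
        lines = [
            "Time-variant VAR (multi-trial Kalman filter)",
            "=" * 46,
            f"channels:        {self.D} ({', '.join(self.channel_names)})",
            f"model order p:   {self.p}",
            f"samples:         {self.n_samples} @ {self.fs:g} Hz",
            f"trials fused:    {self.model.data.shape[0]}",
            f"c1 (innov. adapt): {self.model.config.c1:g}",
            f"c2 (random walk):  {self.model.config.c2:g}",
            f"stable (rho<1):  {self.is_stable()}",
            f"mean resid. var: {self.sigma2[self.p:].mean():.4g} µV²",
        ]
        return "\n".join(lines)


def grand_mean_model(results: list[TvMVARResults]) -> TvMVARResults:
    """Grand-mean model: average coefficient trajectories across subjects.

    Averaging the AR parameters (and residual variances) in the
    coefficient domain before any connectivity transform suppresses
    estimation noise by √n_subjects without the positive bias that
    averaging magnitude-valued PDC maps would retain; group-level
    networks are derived from this grand model.
    """
    if not results:
        raise ValueError("need at least one fitted model")
    ref = results[0]
    for r in results[1:]:
        if r.A.shape != ref.A.shape or r.channel_names != ref.channel_names:
            raise ValueError("models have mismatching shapes or channels")
    A = np.mean([r.A for r in results], axis=0)
    sigma2 = np.mean([r.sigma2 for r in results], axis=0)
    return TvMVARResults(ref.model, A, sigma2)


def select_order(
    epochs: MultiTrialRecording,
    p_range: range | list[int] = range(1, 21),
    exclude_channels: tuple[str, ...] = ("EOG",),
) -> tuple[int, dict[int, float]]:
    """Akaike order selection on a stationary pooled VAR fit.

    Fits an ordinary (time-invariant) VAR(p) by least squares pooled
    across all trials for each candidate order and evaluates

        AIC(p) = N·ln det(Σ̂_p) + 2·p·D²,

    where Σ̂_p is the residual covariance and N the number of pooled
    observations.  Returns ``(best_p, {p: AIC})``.  In the balancing
    study this criterion guides, but the operating order is ultimately
    fixed by configuration.
    """
    keep = [i for i, c in enumerate(epochs.channel_names) if c not in exclude_channels]
    data = epochs.data[:, :, keep, :]
    S, R, D, T = data.shape
    X = data.reshape(S * R, D, T)
    p_max = max(p_range)
    if p_max >= T / 2:
        raise ValueError("max order must be below half the epoch length")

    aic: dict[int, float] = {}
    for p in p_range:
        # condition every candidate on the same samples (t >= p_max) so
        # the likelihoods are comparable across orders
        Y = []
        Z = []
        for trial in range(S * R):
            x = X[trial]
            Y.append(x[:, p_max:].T)  # (T-p_max, D)
            lags = np.stack(
                [x[:, p_max - k : T - k].T for k in range(1, p + 1)], axis=1
            )
            Z.append(lags.reshape(T - p_max, p * D))
        Yc = np.concatenate(Y)
        Zc = np.concatenate(Z)
        N = Yc.shape[0]
        B, *_ = np.linalg.lstsq(Zc, Yc, rcond=None)
        resid = Yc - Zc @ B
        cov = resid.T @ resid / N
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            warnings.warn(f"non-positive-definite residual covariance at p={p}; skipped")
            continue
        aic[p] = float(N * logdet + 2 * p * D * D)
    if not aic:
        raise ValueError("no candidate order produced a valid fit")
    best = min(aic, key=aic.get)
    return best, aic
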