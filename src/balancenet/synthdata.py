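"""Synthetic multi-subject balance-EEG generator with known ground truth.

Emulates the balancing experiment: subjects stand on a platform that is
held stable (BSS) and released at a known onset into free oscillation
(BUS).  Each simulated dataset contains, per subject and trial, an 8 s
multi-channel epoch with

* narrow-band neural oscillators (theta ~6 Hz centro-parietal, alpha
  ~10 Hz occipito-parietal) realized as AR(2) resonators inside a
  time-varying vector-autoregressive (VAR) recursion,
* planted directed couplings injected as band-limited AR cross-terms
  whose gain switches at the onset — the ground truth that the
  Kalman-tvMVAR/gPDC stages are meant to recover,
* a sway-related interference at f0 (default 2.6 Hz) plus harmonics,
  phase-locked to the onset across trials,
* an impulse-like onset artifact, a post-onset alpha amplitude drop,
  stereotyped ocular blinks propagated into the scalp channels, and
  broadband sensor noise.

The neural VAR runs at the analysis rate (``fs_out``); when
``fs_raw > fs_out`` the neural trace is polyphase-upsampled and the
sensor-level components (noise, sway, impulse, EOG) are synthesized at
``fs_raw``, so the decimation stage of the preprocessing chain operates
on genuinely broadband data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .datatypes import MultiTrialRecording, PlatformTrace

__all__ = [
    "Coupling",
    "Oscillator",
    "SwayInterference",
    "SimulationConfig",
    "simulate_dataset",
    "simulate_platform",
    "DEFAULT_SUBSET",
    "FULL_1010_LAYOUT",
]

# 11-channel centro-parietal/occipital subset used for the tensor analyses;
# fast default for the full pipeline.
DEFAULT_SUBSET = ["C1", "Cz", "C2", "CP1", "CPz", "CP2", "P7", "P8", "O1", "Oz", "O2"]

# Full 32-channel 10:10 montage (acquisition reference FCz, ground AFz).
FULL_1010_LAYOUT = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "CP5", "CP1", "CPz", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8", "POz", "O1", "Oz", "O2", "C1", "C2",
]

EOG_NAME = "EOG"


@dataclass(frozen=True)
class Coupling:
    """Directed AR coupling planted between two channels.

    The source drives the target through a band-limited FIR kernel placed
    at ``lag`` samples (at the analysis rate); the kernel gain steps from
    ``pre_gain`` to ``post_gain`` at the onset (optionally ramped).
    """

    source: str
    target: str
    band: tuple[float, float]  # Hz
    pre_gain: float
    post_gain: float
    lag: int = 2  # samples at fs_out
    n_taps: int = 5


@dataclass(frozen=True)
class Oscillator:
    """AR(2) resonator component on a set of channels."""

    channels: tuple[str, ...]
    freq: float  # Hz
    amplitude: float  # µV (RMS·√2 of the stationary oscillation)
    damping: float = 0.85  # pole radius; ~0.85 gives an EEG-like few-Hz bandwidth


@dataclass(frozen=True)
class SwayInterference:
    f0: float = 2.6  # Hz
    n_harmonics: int = 4
    amplitude: float = 3.0  # µV, fundamental; harmonic k scaled by 1/k
    phase_locked: bool = True


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic dataset.

    Defaults reproduce the study conditions: 37 subjects × 10 trials,
    1000 Hz acquisition analysed at 100 Hz, 8 s epochs with the
    stable→unstable transition at 3 s, theta/alpha oscillators, a
    phase-locked 2.6 Hz sway interference with 4 harmonics, an onset
    impulse and a post-onset occipital alpha drop.
    """

    n_subjects: int = 37
    n_trials: int = 10
    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_SUBSET))
    fs_raw: float = 1000.0
    fs_out: float = 100.0
    epoch_length: float = 8.0
    onset_time: float = 3.0
    couplings: list[Coupling] = field(
        default_factory=lambda: [
            Coupling("CPz", "Cz", (5.0, 7.0), pre_gain=0.0, post_gain=0.4, lag=2)
        ]
    )
    oscillators: list[Oscillator] = field(
        default_factory=lambda: [
            Oscillator(("C1", "Cz", "C2", "CP1", "CPz", "CP2"), 6.0, 7.5),
            Oscillator(("P7", "P8", "O1", "Oz", "O2"), 10.0, 10.0),
        ]
    )
    sway: SwayInterference = field(default_factory=SwayInterference)
    onset_impulse_amplitude: float = 20.0  # µV
    alpha_drop: tuple[float, float] = (0.5, 2.0)  # (depth fraction, duration s)
    alpha_drop_band: tuple[float, float] = (8.0, 12.0)  # oscillators affected
    noise_sd: float = 4.0  # µV broadband sensor noise at fs_raw (~1.6 µV after decimation)
    background_sd: float = 1.0  # µV innovation of the neural VAR background
    eog_blink_rate: float = 0.2  # blinks per second
    eog_propagation: float | dict[str, float] = 0.05
    include_eog: bool = True
    gain_ramp: float = 0.0  # s; 0 = step transition at onset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_raw % self.fs_out:
            raise ValueError("fs_raw must be an integer multiple of fs_out")
        if not 0 < self.onset_time < self.epoch_length:
            raise ValueError("onset_time must lie strictly inside the epoch")
        for c in self.couplings:
            for ch in (c.source, c.target):
                if ch not in self.channel_names:
                    raise ValueError(f"coupling channel {ch!r} not in channel_names")
        # oscillators may name channels absent from a reduced montage;
        # they are silently inactive there

    @property
    def decim_factor(self) -> int:
        return int(round(self.fs_raw / self.fs_out))

    @property
    def n_samples_out(self) -> int:
        return int(round(self.epoch_length * self.fs_out))

    @property
    def n_samples_raw(self) -> int:
        return int(round(self.epoch_length * self.fs_raw))

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# --------------------------------------------------------------------------
# VAR construction
# --------------------------------------------------------------------------

def _ar2_coeffs(freq: float, damping: float, fs: float) -> tuple[float, float]:
    """AR(2) resonator coefficients for a spectral peak at ``freq``."""
    theta = 2.0 * np.pi * freq / fs
    a1 = 2.0 * damping * np.cos(theta)
    a2 = -damping * damping
    return a1, a2


def _ar2_innovation_sd(amplitude: float, a1: float, a2: float) -> float:
    """Innovation SD so the stationary AR(2) output has RMS amplitude/√2."""
    target_var = amplitude**2 / 2.0
    # stationary variance of AR(2): var = s² (1−a2) / ((1+a2)((1−a2)²−a1²))
    gain = (1.0 - a2) / ((1.0 + a2) * ((1.0 - a2) ** 2 - a1**2))
    if gain <= 0:
        raise ValueError("unstable AR(2) resonator")
    return float(np.sqrt(target_var / gain))


def _bandpass_kernel(band: tuple[float, float], gain: float, n_taps: int, fs: float) -> np.ndarray:
    """Short FIR bandpass kernel with peak in-band gain ``gain``."""
    if gain == 0.0:
        return np.zeros(n_taps)
    lo, hi = band
    h = signal.firwin(n_taps, [lo, hi], pass_zero=False, fs=fs, window="hamming")
    f, resp = signal.freqz(h, worN=512, fs=fs)
    inband = (f >= lo) & (f <= hi)
    peak = np.abs(resp[inband]).max()
    return h * (gain / peak)


def build_var_coefficients(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre- and post-onset VAR coefficient stacks and innovation SDs.

    Returns ``(A_pre, A_post, innov_sd)`` where the ``A`` stacks have shape
    ``(p, D, D)`` (lag-major; scalp channels only) and ``innov_sd`` has
    shape ``(D,)``.
    """
    names = cfg.channel_names
    D = len(names)
    max_lag = 2
    for c in cfg.couplings:
        max_lag = max(max_lag, c.lag + c.n_taps)
    p = max_lag
    A_pre = np.zeros((p, D, D))
    A_post = np.zeros((p, D, D))
    innov_sd = np.full(D, cfg.background_sd, float)

    for osc in cfg.oscillators:
        a1, a2 = _ar2_coeffs(osc.freq, osc.damping, cfg.fs_out)
        sd = _ar2_innovation_sd(osc.amplitude, a1, a2)
        for ch in osc.channels:
            if ch not in names:
                continue
            i = names.index(ch)
            A_pre[0, i, i] = a1
            A_pre[1, i, i] = a2
            A_post[0, i, i] = a1
            A_post[1, i, i] = a2
            innov_sd[i] = sd

    for c in cfg.couplings:
        i = names.index(c.target)
        j = names.index(c.source)
        for which, g in ((A_pre, c.pre_gain), (A_post, c.post_gain)):
            h = _bandpass_kernel(c.band, g, c.n_taps, cfg.fs_out)
            which[c.lag : c.lag + c.n_taps, i, j] += h

    return A_pre, A_post, innov_sd


def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the companion matrix of a VAR coefficient stack."""
    p, D, _ = A.shape
    comp = np.zeros((p * D, p * D))
    comp[:D] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[D:, : D * (p - 1)] = np.eye(D * (p - 1))
    return float(np.abs(np.linalg.eigvals(comp)).max())


def _check_stability(cfg: SimulationConfig, A_pre: np.ndarray, A_post: np.ndarray) -> None:
    for label, A, t in (("pre-onset", A_pre, 0.0), ("post-onset", A_post, cfg.onset_time)):
        rho = companion_spectral_radius(A)
        if rho >= 1.0:
            raise ValueError(
                f"planted VAR system is unstable ({label}, t={t:g} s): "
                f"companion spectral radius {rho:.4f} >= 1"
            )


# --------------------------------------------------------------------------
# Component synthesis
# --------------------------------------------------------------------------

def _simulate_var(
    cfg: SimulationConfig,
    A_pre: np.ndarray,
    A_post: np.ndarray,
    innov_sd: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Time-varying VAR recursion at fs_out for all subjects × trials.

    Returns array of shape (S, R, D, T_out).
    """
    S, R = cfg.n_subjects, cfg.n_trials
    D = len(cfg.channel_names)
    T = cfg.n_samples_out
    p = A_pre.shape[0]
    onset = int(round(cfg.onset_time * cfg.fs_out))
    B = S * R

    drop_depth, drop_dur = cfg.alpha_drop
    drop_lo, drop_hi = cfg.alpha_drop_band
    drop_idx = [
        cfg.channel_names.index(ch)
        for osc in cfg.oscillators
        if drop_lo <= osc.freq <= drop_hi
        for ch in osc.channels
        if ch in cfg.channel_names
    ]
    drop_end = min(T, onset + int(round(drop_dur * cfg.fs_out)))

    sd_t = np.broadcast_to(innov_sd, (T, D)).copy()
    if drop_idx and drop_depth > 0:
        sd_t[onset:drop_end, drop_idx] *= 1.0 - drop_depth

    noise = rng.standard_normal((T, B, D)) * sd_t[:, None, :]

    ramp_n = int(round(cfg.gain_ramp * cfg.fs_out))
    x = np.zeros((T + p, B, D))
    for t in range(T):
        if ramp_n > 0 and onset <= t < onset + ramp_n:
            w = (t - onset + 1) / ramp_n
            A = (1 - w) * A_pre + w * A_post
        else:
            A = A_post if t >= onset else A_pre
        xlag = x[t : t + p][::-1]  # p most recent lags, newest (lag 1) first
        x[t + p] = np.einsum("kij,kbj->bi", A, xlag) + noise[t]
    out = x[p:]  # (T, B, D)
    return out.transpose(1, 2, 0).reshape(S, R, D, T)


def _biphasic_pulse(width_s: float, fs: float) -> np.ndarray:
    """Derivative-of-Gaussian biphasic pulse, unit peak amplitude."""
    n = int(round(width_s * fs))
    t = np.linspace(-3, 3, n)
    pulse = -t * np.exp(-0.5 * t**2)
    return pulse / np.abs(pulse).max()


def _sway_component(
    cfg: SimulationConfig, rng: np.random.Generator, phases: np.ndarray | None
) -> np.ndarray:
    """Sway interference trace at fs_raw for one trial (1D, length n_raw)."""
    sway = cfg.sway
    T = cfg.n_samples_raw
    t = np.arange(T) / cfg.fs_raw
    on = t >= cfg.onset_time
    # short cosine ramp so the interference grows over ~0.2 s
    env = np.zeros(T)
    ramp = 0.2
    rel = (t[on] - cfg.onset_time) / ramp
    env[on] = np.where(rel < 1.0, 0.5 * (1 - np.cos(np.pi * rel)), 1.0)
    if phases is None:
        phases = rng.uniform(0, 2 * np.pi, sway.n_harmonics)
    s = np.zeros(T)
    for k in range(1, sway.n_harmonics + 1):
        s += (sway.amplitude / k) * np.sin(
            2 * np.pi * k * sway.f0 * (t - cfg.onset_time) + phases[k - 1]
        )
    return s * env


def _eog_signals(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Blink trace (S, R, T_raw) and per-channel propagation coefficients."""
    S, R, T = cfg.n_subjects, cfg.n_trials, cfg.n_samples_raw
    pulse = _biphasic_pulse(0.3, cfg.fs_raw)
    eog = np.zeros((S, R, T))
    n_exp = cfg.eog_blink_rate * cfg.epoch_length
    for s in range(S):
        for r in range(R):
            n_blinks = rng.poisson(n_exp)
            starts = rng.integers(0, max(1, T - len(pulse)), size=n_blinks)
            amps = 100.0 * rng.uniform(0.7, 1.3, size=n_blinks)
            for st, a in zip(starts, amps):
                eog[s, r, st : st + len(pulse)] += a * pulse[: T - st]
    if isinstance(cfg.eog_propagation, dict):
        prop = np.array([cfg.eog_propagation.get(ch, 0.0) for ch in cfg.channel_names])
    else:
        prop = np.full(len(cfg.channel_names), float(cfg.eog_propagation))
    return eog, prop


# --------------------------------------------------------------------------
# Public entry points
# --------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> MultiTrialRecording:
    """Generate a synthetic multi-subject recording at ``fs_raw``.

    Deterministic given ``config.seed``.  The returned recording carries
    the config as ``ground_truth`` and the onset sample index; it is meant
    to be pushed through the preprocessing chain (common-average
    reference, ocular correction, decimation to ``fs_out``) before model
    fitting.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    A_pre, A_post, innov_sd = build_var_coefficients(cfg)
    _check_stability(cfg, A_pre, A_post)

    neural = _simulate_var(cfg, A_pre, A_post, innov_sd, rng)  # (S,R,D,T_out)
    S, R, D, _ = neural.shape
    T_raw = cfg.n_samples_raw
    factor = cfg.decim_factor
    if factor > 1:
        neural_raw = signal.resample_poly(neural, factor, 1, axis=-1)
        neural_raw = neural_raw[..., :T_raw]
    else:
        neural_raw = neural

    data = neural_raw + rng.standard_normal((S, R, D, T_raw)) * cfg.noise_sd

    # sway interference: per-dataset topography weights; phase-locked across
    # trials (same harmonic phases at onset) when flagged
    if cfg.sway.amplitude > 0 and cfg.sway.n_harmonics > 0:
        topo = rng.uniform(0.5, 1.0, D)
        locked_phases = rng.uniform(0, 2 * np.pi, cfg.sway.n_harmonics)
        for s in range(S):
            for r in range(R):
                ph = locked_phases if cfg.sway.phase_locked else None
                data[s, r] += topo[:, None] * _sway_component(cfg, rng, ph)[None, :]

    # impulse-like onset artifact on all channels
    if cfg.onset_impulse_amplitude > 0:
        pulse = _biphasic_pulse(0.05, cfg.fs_raw) * cfg.onset_impulse_amplitude
        i0 = int(round(cfg.onset_time * cfg.fs_raw)) - len(pulse) // 2
        i0 = max(i0, 0)
        seg = slice(i0, min(i0 + len(pulse), T_raw))
        imp_topo = rng.uniform(0.8, 1.2, D)
        data[..., seg] += imp_topo[:, None] * pulse[: seg.stop - seg.start]

    names = list(cfg.channel_names)
    if cfg.include_eog:
        eog, prop = _eog_signals(cfg, rng)
        data += prop[None, None, :, None] * eog[:, :, None, :]
        eog_chan = eog + rng.standard_normal(eog.shape) * cfg.noise_sd
        data = np.concatenate([data, eog_chan[:, :, None, :]], axis=2)
        names = names + [EOG_NAME]

    onset_sample = int(round(cfg.onset_time * cfg.fs_raw))
    return MultiTrialRecording(
        data=data,
        fs=cfg.fs_raw,
        channel_names=names,
        onset_sample=onset_sample,
        ground_truth=cfg,
    )


def simulate_platform(
    fs: float,
    duration: float,
    release_time: float,
    seed: int = 0,
    baseline_sd: float = 0.02,
    oscillation_amplitude: float = 1.0,
    f0: float = 2.6,
) -> PlatformTrace:
    """Simulate a platform displacement trace for one 30 s balancing trial.

    Quiescent low-variance baseline while the anchor holds the platform;
    after ``release_time`` the platform settles into a sustained
    oscillation around ``f0`` whose amplitude rises within ~50 ms, so a
    5-SD threshold rule triggers essentially at release.
    """
    if not 0 < release_time < duration:
        raise ValueError("release_time must lie strictly inside the trace")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    release = int(round(release_time * fs))

    # smoothed measurement noise baseline on both axes
    base = rng.standard_normal((2, n)) * baseline_sd
    if fs > 40:
        b, a = signal.butter(2, 20.0, fs=fs)
        base = signal.filtfilt(b, a, base, axis=1)

    disp = base.copy()
    post = t >= release_time
    tau = 0.05  # s rise time of the oscillation envelope
    env = 1.0 - np.exp(-(t[post] - release_time) / tau)
    am = 1.0 + 0.2 * np.sin(2 * np.pi * 0.3 * (t[post] - release_time))
    ml = oscillation_amplitude * env * am * np.sin(2 * np.pi * f0 * (t[post] - release_time))
    ap = 0.4 * oscillation_amplitude * env * am * np.sin(
        2 * np.pi * f0 * (t[post] - release_time) + np.pi / 3
    )
    # anchor release induces a medial platform shift
    disp[0, post] += 0.5 * oscillation_amplitude * env + ml
    disp[1, post] += ap
    return PlatformTrace(displacement=disp, fs=fs, true_release_sample=release)
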