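"""Time–frequency analysis: multi-window (matched) Gabor transform,
phase-locking index, Rayleigh thresholding and phase-locked-harmonic
artifact screening.

The matched Gabor transform (MGT) used here evaluates a Gabor filter
bank at several window widths and keeps, per time–frequency tile, the
coefficient from the window with the highest local amplitude
concentration.  Amplitudes are calibrated so a unit-amplitude sinusoid
yields 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeFrequencyMap",
    "GaborDictionary",
    "ArtifactScreenConfig",
    "mgt",
    "pli",
    "rayleigh_threshold",
    "threshold_pli",
    "screen_harmonics",
]


@dataclass
class TimeFrequencyMap:
    """2-D map over time and frequency.

    ``kind`` is one of ``"amplitude"`` (µV), ``"phase"`` (rad), ``"pli"``
    (unitless in [0, 1]) or ``"binary"`` (0/1 significance mask).
    """

    values: np.ndarray  # (n_times, n_freqs)
    times: np.ndarray  # s
    freqs: np.ndarray  # Hz
    kind: str = "amplitude"
    channel: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.times = np.asarray(self.times, float)
        self.freqs = np.asarray(self.freqs, float)
        if self.values.shape != (self.times.size, self.freqs.size):
            raise ValueError("values must be (n_times, n_freqs)")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.freqs.size > 1 and not np.all(np.diff(self.freqs) > 0):
            raise ValueError("freqs must be strictly increasing")
        if self.kind == "pli" and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("PLI values must lie in [0, 1]")
        if self.kind == "binary" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("binary map must contain only 0/1")

    def plot(self, ax=None, cmap: str = "viridis", vmax: float | None = None):
        """Render the map as a time–frequency image (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.pcolormesh(self.times, self.freqs, self.values.T,
                           cmap=cmap, vmax=vmax, shading="auto")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        if self.channel:
            ax.set_title(f"{self.channel} ({self.kind})")
        ax.figure.colorbar(im, ax=ax)
        return ax

    def band_mean(self, f_lo: float, f_hi: float) -> np.ndarray:
        """Time course of the mean over a frequency band [f_lo, f_hi]."""
        sel = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        if not sel.any():
            raise ValueError("band contains no frequency bins")
        return self.values[:, sel].mean(axis=1)


@dataclass(frozen=True)
class GaborDictionary:
    """Gaussian-window dictionary for the multi-window Gabor transform.

    ``window_widths`` are the Gaussian FWHM-like width parameters in
    seconds (each window's SD is width/2); the widest window bounds the
    temporal smoothing, the narrowest the frequency smoothing.
    """

    window_widths: tuple[float, ...] = (0.25, 0.5, 1.0)
    hop: float = 0.01  # s
    freq_grid: tuple[float, float, float] = (0.5, 30.0, 0.5)  # lo, hi, step

    def __post_init__(self) -> None:
        if not self.window_widths:
            raise ValueError("empty Gabor dictionary")
        if any(w <= 0 for w in self.window_widths):
            raise ValueError("window widths must be positive")
        if list(self.window_widths) != sorted(self.window_widths):
            raise ValueError("window widths must be sorted ascending")

    @property
    def freqs(self) -> np.ndarray:
        lo, hi, step = self.freq_grid
        return np.arange(lo, hi + step / 2, step)


def _gabor_filter_bank(x: np.ndarray, fs: float, freqs: np.ndarray, width: float) -> np.ndarray:
    """Complex Gabor coefficients for one window width.

    Returns (n_samples, n_freqs) complex; amplitude-calibrated so
    ``2 * |coef|`` of a unit sinusoid is ~1... calibration is folded in:
    the returned coefficients already carry the 2/Σw factor.
    """
    sd = width / 2.0
    half = int(np.ceil(4 * sd * fs))
    t = np.arange(-half, half + 1) / fs
    win = np.exp(-0.5 * (t / sd) ** 2)
    norm = 2.0 / win.sum()
    out = np.empty((x.size, freqs.size), complex)
    n_fft = int(2 ** np.ceil(np.log2(x.size + win.size)))
    X = np.fft.fft(x, n_fft)
    for k, f in enumerate(freqs):
        # correlation with win(τ)·e^{−i2πfτ} == convolution with win(τ)·e^{+i2πfτ}
        kern = win * np.exp(1j * 2 * np.pi * f * t)
        conv = np.fft.ifft(X * np.fft.fft(kern, n_fft))
        out[:, k] = norm * conv[half : half + x.size]
    return out


def mgt(
    x: np.ndarray,
    fs: float,
    dictionary: GaborDictionary | None = None,
    channel: str | None = None,
) -> tuple[TimeFrequencyMap, TimeFrequencyMap]:
    """Matched Gabor transform of a single-trial signal.

    For every time–frequency tile the Gabor coefficient is computed under
    each window width in the dictionary and the one with the largest
    amplitude (best local concentration of signal energy under that
    window) is kept; amplitude and phase maps share the matched window.

    Returns ``(amplitude_map, phase_map)`` on the dictionary's grid.
    """
    d = dictionary or GaborDictionary()
    x = np.asarray(x, float)
    freqs = d.freqs
    widest = int(np.ceil(4 * max(d.window_widths) * fs)) * 2 + 1
    if x.size <= widest // 4:
        raise ValueError("signal shorter than the widest analysis window")

    hop = max(1, int(round(d.hop * fs)))
    idx = np.arange(0, x.size, hop)
    times = idx / fs

    best_amp = None
    best_coef = None
    for w in d.window_widths:
        coef = _gabor_filter_bank(x, fs, freqs, w)[idx]
        amp = np.abs(coef)
        if best_amp is None:
            best_amp, best_coef = amp, coef
        else:
            take = amp > best_amp
            best_amp = np.where(take, amp, best_amp)
            best_coef = np.where(take, coef, best_coef)

    amp_map = TimeFrequencyMap(best_amp, times, freqs, "amplitude", channel)
    phase_map = TimeFrequencyMap(np.angle(best_coef), times, freqs, "phase", channel)
    return amp_map, phase_map


def pli(phase_maps: list[TimeFrequencyMap]) -> TimeFrequencyMap:
    """Phase-locking index across trials.

    ``PLI(t, f) = | mean_trials exp(i·phase(t, f)) |`` — 1 means every
    trial carries the same phase at that tile, 0 means uniform phases.
    """
    if len(phase_maps) < 2:
        raise ValueError("PLI needs at least 2 trials")
    ref = phase_maps[0]
    for m in phase_maps[1:]:
        if m.values.shape != ref.values.shape:
            raise ValueError("trial phase maps have mismatching shapes")
    stack = np.stack([m.values for m in phase_maps])
    r = np.abs(np.exp(1j * stack).mean(axis=0))
    return TimeFrequencyMap(np.clip(r, 0.0, 1.0), ref.times, ref.freqs, "pli", ref.channel)


def rayleigh_threshold(n_trials: int, alpha: float = 0.05) -> float:
    """Critical PLI value of the (large-sample) Rayleigh uniformity test.

    Under uniform phases, ``n·PLI²`` is asymptotically exponential, so the
    level-``alpha`` critical value is ``sqrt(-ln(alpha) / n)``.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(np.sqrt(-np.log(alpha) / n_trials))


def threshold_pli(pli_map: TimeFrequencyMap, n_trials: int, alpha: float = 0.05) -> TimeFrequencyMap:
    """Binary significance map: 1 where PLI exceeds the Rayleigh threshold."""
    crit = rayleigh_threshold(n_trials, alpha)
    binary = (pli_map.values > crit).astype(float)
    return TimeFrequencyMap(binary, pli_map.times, pli_map.freqs, "binary", pli_map.channel)


@dataclass(frozen=True)
class ArtifactScreenConfig:
    """Screening for phase-locked sway-interference harmonics.

    The sway interference rides at ``f0`` and, being phase-locked to the
    onset, shows up in the binary PLI map at ``f0`` and its harmonics.
    Any analysis band within ``guard_band`` Hz of a flagged harmonic is
    declared contaminated.
    """

    f0: float = 2.6
    n_harmonics: int = 4
    alpha: float = 0.05
    guard_band: float = 1.0
    post_onset_window: tuple[float, float] = (3.5, 8.0)  # s
    min_significant_fraction: float = 0.5
    bands: dict = field(
        default_factory=lambda: {"theta": (5.0, 7.0), "alpha": (9.0, 11.0)}
    )

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def screen_harmonics(
    binary_map: TimeFrequencyMap, cfg: ArtifactScreenConfig | None = None
) -> dict:
    """Flag phase-locked harmonics of the sway interference.

    For each harmonic ``k·f0`` the fraction of significant bins in the
    post-onset window (within ``guard_band`` of the harmonic frequency)
    is computed; harmonics exceeding ``min_significant_fraction`` are
    flagged.  Each analysis band is declared ``"contaminated"`` if a
    flagged harmonic lies within ``guard_band`` of the band, else
    ``"clean"``.

    Returns a dict with ``flagged`` (list of (frequency, time-interval)
    regions), ``fractions`` per harmonic, and ``verdicts`` per band.
    """
    cfg = cfg or ArtifactScreenConfig()
    if binary_map.kind != "binary":
        raise ValueError("screen_harmonics expects a binary PLI map")
    t_lo, t_hi = cfg.post_onset_window
    tsel = (binary_map.times >= t_lo) & (binary_map.times < t_hi)
    flagged: list[tuple[float, tuple[float, float]]] = []
    fractions: dict[float, float] = {}
    for k in range(1, cfg.n_harmonics + 1):
        fk = k * cfg.f0
        fsel = np.abs(binary_map.freqs - fk) <= cfg.guard_band / 2
        if not fsel.any() or not tsel.any():
            fractions[fk] = 0.0
            continue
        # per-bin persistence within the guard window; the harmonic is as
        # contaminated as its most persistent nearby frequency bin
        frac = float(binary_map.values[np.ix_(tsel, fsel)].mean(axis=0).max())
        fractions[fk] = frac
        if frac >= cfg.min_significant_fraction:
            flagged.append((fk, (t_lo, t_hi)))

    verdicts = {}
    for name, (b_lo, b_hi) in cfg.bands.items():
        contaminated = any(
            b_lo - cfg.guard_band <= fk <= b_hi + cfg.guard_band for fk, _ in flagged
        )
        verdicts[name] = "contaminated" if contaminated else "clean"
    return {"flagged": flagged, "fractions": fractions, "verdicts": verdicts}
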