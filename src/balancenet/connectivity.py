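"""Time-variant generalized partial directed coherence and directed
network statistics.

Direction convention (used everywhere, including exports): ``π(i←j)``
quantifies the influence of source channel j (column) on target channel
i (row).  For a VAR transfer polynomial Ā(f, t) = I − Σ_k A_k(t)e^{−i2πfk/fs},

    π(i←j, t, f) = (|Ā_ij(f,t)| / σ_i) / sqrt( Σ_m |Ā_mj(f,t)|² / σ_m² ),

the residual-variance normalization making the measure scale invariant.
Columns are normalized: Σ_i π(i←j)² = 1 for every source j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tvmvar import TvMVARResults

__all__ = [
    "PDCTensor",
    "ROISpec",
    "DirectedNetwork",
    "gpdc",
    "gpdc_from_coefficients",
    "roi_mean",
    "discretize",
    "node_strength",
    "average_node_strength",
    "condition_ans",
    "THETA_BAND",
    "ALPHA_BAND",
    "TIME_INTERVALS",
]

THETA_BAND = (5.0, 7.0)
ALPHA_BAND = (9.0, 11.0)
# analysis intervals after the onset (epoch-local seconds); the first
# 0.5 s after the onset is excluded as motion-artifact-dominated
TIME_INTERVALS = {
    "TI1": (3.5, 4.5),
    "TI2": (4.5, 5.5),
    "TI3": (5.5, 6.5),
    "TI4": (6.5, 7.5),
}


@dataclass
class PDCTensor:
    """Directed connectivity values π(i←j, t, f) for all ordered pairs.

    ``values`` has shape (D_target, D_source, n_times, n_freqs) with the
    diagonal retained (the network-facing accessor :meth:`offdiagonal`
    zeroes it).
    """

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        D = len(self.channel_names)
        if self.values.shape[:2] != (D, D):
            raise ValueError("values must be (D, D, n_times, n_freqs)")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-9:
            raise ValueError("gPDC values must lie in [0, 1]")

    @property
    def D(self) -> int:
        return len(self.channel_names)

    def column_norms(self) -> np.ndarray:
        """Σ_target π² per (source, t, f); equals 1 for a valid tensor."""
        return (self.values**2).sum(axis=0)

    def offdiagonal(self) -> np.ndarray:
        """Copy of the values with the self-connectivity diagonal zeroed."""
        out = self.values.copy()
        i = np.arange(self.D)
        out[i, i] = 0.0
        return out


@dataclass(frozen=True)
class ROISpec:
    """Region of interest: a frequency band × time interval box."""

    band: tuple[float, float]  # Hz
    interval: tuple[float, float]  # s
    label: str = ""

    def __post_init__(self) -> None:
        if self.band[0] >= self.band[1]:
            raise ValueError("band must satisfy f_lo < f_hi")
        if self.interval[0] >= self.interval[1]:
            raise ValueError("interval must satisfy t_lo < t_hi")


@dataclass
class DirectedNetwork:
    """Weighted directed network built from ROI-mean PDC values.

    Edges are ``(source, target, weight, level)`` with discretization
    levels 1..n assigned by the half-open threshold bins.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float, int]]
    roi: ROISpec | None = None
    thresholds: tuple[float, ...] = (0.08, 0.10, 0.12)

    def to_weight_matrix(self) -> np.ndarray:
        """(target, source) weight matrix of the retained edges."""
        D = len(self.nodes)
        W = np.zeros((D, D))
        idx = {n: i for i, n in enumerate(self.nodes)}
        for src, tgt, w, _ in self.edges:
            W[idx[tgt], idx[src]] = w
        return W

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.edges, columns=["source", "target", "weight", "level"])


# --------------------------------------------------------------------------
# gPDC
# --------------------------------------------------------------------------

def gpdc_from_transfer(Abar: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """gPDC from a transfer polynomial Ā (..., D, D) and variances (..., D)."""
    sig = np.sqrt(sigma2)
    num = np.abs(Abar) / sig[..., :, None]  # |Ā_ij| / σ_i
    denom = np.sqrt((num**2).sum(axis=-2, keepdims=True))  # per source column j
    return num / denom


def gpdc(
    results: TvMVARResults,
    freqs: np.ndarray | None = None,
    t_step: int = 1,
) -> PDCTensor:
    """Time-variant gPDC tensor from a fitted time-varying VAR."""
    if freqs is None:
        freqs = np.arange(1.0, 30.5, 0.5)
    freqs = np.asarray(freqs, float)
    Abar, t_index = results.transfer_polynomial(freqs, t_step)  # (nt, nf, D, D)
    sig = results.sigma2[t_index]  # (nt, D)
    if np.any(sig <= 0):
        bad = results.channel_names[int(np.argwhere(sig <= 0)[0][1])]
        raise ValueError(f"zero residual variance for channel {bad}")
    pi = gpdc_from_transfer(Abar, sig[:, None, :])  # (nt, nf, D, D)
    values = np.moveaxis(pi, (2, 3), (0, 1))  # (D, D, nt, nf)
    return PDCTensor(
        values=np.clip(values, 0.0, 1.0),
        times=t_index / results.fs,
        freqs=freqs,
        channel_names=list(results.channel_names),
    )


def gpdc_from_coefficients(
    A: np.ndarray, sigma2: np.ndarray, freqs: np.ndarray, fs: float
) -> np.ndarray:
    """gPDC of a stationary VAR given its true coefficients.

    ``A`` is (p, D, D), ``sigma2`` (D,).  Returns (D, D, n_freqs) —
    useful as ground truth for planted systems.
    """
    A = np.asarray(A, float)
    freqs = np.asarray(freqs, float)
    p, D, _ = A.shape
    k = np.arange(1, p + 1)
    E = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)  # (F, p)
    Abar = np.eye(D) - np.einsum("fk,kij->fij", E, A)
    pi = gpdc_from_transfer(Abar, np.broadcast_to(sigma2, (freqs.size, D)))
    return np.moveaxis(pi, (1, 2), (0, 1))  # (D, D, F)


# --------------------------------------------------------------------------
# ROI means, discretization, node strength
# --------------------------------------------------------------------------

def roi_mean(pdc: PDCTensor, roi: ROISpec) -> np.ndarray:
    """Mean PDC over the ROI box per directed pair; diagonal zeroed.

    Time interval is half-open [t_lo, t_hi); frequency band inclusive.
    """
    tsel = (pdc.times >= roi.interval[0]) & (pdc.times < roi.interval[1])
    fsel = (pdc.freqs >= roi.band[0]) & (pdc.freqs <= roi.band[1])
    if not tsel.any() or not fsel.any():
        raise ValueError(f"ROI {roi.label or roi} selects an empty box")
    mean = pdc.offdiagonal()[:, :, tsel][:, :, :, fsel].mean(axis=(2, 3))
    return mean


def discretize(
    mean_matrix: np.ndarray,
    channel_names: list[str],
    thresholds: tuple[float, ...] = (0.08, 0.10, 0.12),
    roi: ROISpec | None = None,
) -> DirectedNetwork:
    """Build a discretized directed network from an ROI-mean matrix.

    Entries below ``thresholds[0]`` are dropped; level ℓ (1-based) is
    assigned by the half-open bins [t_ℓ, t_{ℓ+1}), boundary values going
    to the upper bin; values ≥ the last threshold get the top level.
    """
    thresholds = tuple(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    D = len(channel_names)
    edges = []
    for i in range(D):  # target
        for j in range(D):  # source
            if i == j:
                continue
            w = float(mean_matrix[i, j])
            if w < thresholds[0]:
                continue
            level = int(np.searchsorted(thresholds, w, side="right"))
            edges.append((channel_names[j], channel_names[i], w, level))
    return DirectedNetwork(nodes=list(channel_names), edges=edges, roi=roi, thresholds=thresholds)


def node_strength(weights: np.ndarray | DirectedNetwork) -> np.ndarray:
    """Node strength s_i = Σ_j (w_ij + w_ji): incoming plus outgoing weight."""
    W = weights.to_weight_matrix() if isinstance(weights, DirectedNetwork) else np.asarray(weights, float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("expected a square weight matrix")
    return W.sum(axis=1) + W.sum(axis=0)


def average_node_strength(weights: np.ndarray | DirectedNetwork) -> float:
    """ANS: arithmetic mean of all node strengths (2·total weight / D)."""
    s = node_strength(weights)
    return float(s.mean())


def condition_ans(
    pdc: PDCTensor, onset_time: float, burn_in: float = 1.0
) -> dict[str, np.ndarray]:
    """Per-frequency ANS during the stable (BSS) and unstable (BUS) period.

    The undiscretized PDC tensor is averaged across time within each
    condition (before vs. after the onset), then the average node
    strength is computed per frequency bin.  The first ``burn_in``
    seconds of the epoch are excluded: the Kalman coefficient trajectory
    is still converging there and its inflated estimation noise would
    leak into the stable-period average.

    Returns ``{"bss": (n_freqs,), "bus": (n_freqs,), "freqs": ...}``.
    """
    t = pdc.times
    if not (t[0] < onset_time < t[-1]):
        raise ValueError("onset_time must lie inside the time axis")
    off = pdc.offdiagonal()
    out = {}
    for name, sel in (
        ("bss", (t >= burn_in) & (t < onset_time)),
        ("bus", t >= onset_time),
    ):
        mean = off[:, :, sel].mean(axis=2)  # (D, D, F)
        strengths = mean.sum(axis=1) + mean.sum(axis=0)  # (D, F)
        out[name] = strengths.mean(axis=0)
    out["freqs"] = pdc.freqs
    return out
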