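"""Group statistics: bootstrap confidence tubes for band-amplitude time
courses and Bonferroni-corrected paired t-tests on average node strength."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BootstrapConfig",
    "TubeResult",
    "confidence_tube",
    "tube_overlap",
    "paired_ttest_ans",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Subject-level bootstrap settings (1000 replicates, 95% tube)."""

    n_replicates: int = 1000
    q_lo: float = 0.025
    q_hi: float = 0.975
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q_lo < self.q_hi < 1:
            raise ValueError("quantiles must satisfy 0 < q_lo < q_hi < 1")


@dataclass
class TubeResult:
    """Pointwise bootstrap confidence tube for a mean time course."""

    lower: np.ndarray
    upper: np.ndarray
    mean: np.ndarray
    times: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")

    def contains(self, course: np.ndarray) -> np.ndarray:
        """Pointwise: does the tube contain the given time course?"""
        c = np.asarray(course, float)
        return (c >= self.lower) & (c <= self.upper)


def confidence_tube(
    courses: np.ndarray,
    cfg: BootstrapConfig | None = None,
    times: np.ndarray | None = None,
    label: str = "",
) -> TubeResult:
    """Bootstrap confidence tube of the across-subject mean time course.

    ``courses`` has shape (n_subjects, n_times).  Subjects are resampled
    with replacement ``n_replicates`` times; each replicate's mean time
    course contributes to the pointwise [q_lo, q_hi] quantile tube.
    """
    cfg = cfg or BootstrapConfig()
    courses = np.atleast_2d(np.asarray(courses, float))
    n = courses.shape[0]
    if n < 3:
        raise ValueError("confidence tube requires at least 3 subjects")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, n, size=(cfg.n_replicates, n))
    boot_means = courses[idx].mean(axis=1)  # (n_replicates, n_times)
    lower, upper = np.quantile(boot_means, [cfg.q_lo, cfg.q_hi], axis=0)
    return TubeResult(lower=lower, upper=upper, mean=courses.mean(axis=0), times=times, label=label)


def tube_overlap(tube_a: TubeResult, tube_b: TubeResult) -> np.ndarray:
    """Pointwise boolean: do the two tubes intersect at each time point?

    Non-overlap at a time point is the study's criterion for a
    significant condition difference there.
    """
    if tube_a.lower.shape != tube_b.lower.shape:
        raise ValueError("tubes have mismatching time axes")
    if tube_a.times is not None and tube_b.times is not None:
        if not np.allclose(tube_a.times, tube_b.times):
            raise ValueError("tubes have mismatching time axes")
    return (tube_a.lower <= tube_b.upper) & (tube_b.lower <= tube_a.upper)


def paired_ttest_ans(
    ans_bss: np.ndarray,
    ans_bus: np.ndarray,
    freqs: np.ndarray | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-test of per-frequency ANS between conditions, Bonferroni-
    corrected over frequency bins.

    ``ans_bss``/``ans_bus`` have shape (n_subjects, n_bins).  Returns a
    tidy table with columns ``freq, t, p, significant`` where
    significance is assessed two-sided at ``alpha / n_bins``.
    """
    a = np.atleast_2d(np.asarray(ans_bss, float))
    b = np.atleast_2d(np.asarray(ans_bus, float))
    if a.shape != b.shape:
        raise ValueError("condition arrays must have equal shapes")
    n, n_bins = a.shape
    if n < 2:
        raise ValueError("paired t-test requires at least 2 subjects")
    d = b - a
    sd = d.std(axis=0, ddof=1)
    tvals = np.empty(n_bins)
    pvals = np.empty(n_bins)
    for k in range(n_bins):
        if sd[k] == 0.0:
            if np.all(d[:, k] == 0.0):
                tvals[k], pvals[k] = 0.0, 1.0
            else:
                raise ValueError(f"exact tie with zero difference variance in bin {k}")
        else:
            tvals[k], pvals[k] = sps.ttest_rel(b[:, k], a[:, k])
    significant = pvals < alpha / n_bins
    return pd.DataFrame(
        {
            "freq": np.arange(n_bins) if freqs is None else np.asarray(freqs),
            "t": tvals,
            "p": pvals,
            "significant": significant,
        }
    )
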