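"""Preprocessing chain: onset detection, epoching, re-referencing,
regression-based ocular correction, decimation.

The chain mirrors standard event-related EEG practice for perturbation
experiments: the platform-release onset is found on the motion trace with
a 5-SD rule, 8 s epochs are cut around it (3 s pre / 5 s post), data are
re-referenced to the common average, ocular activity is regressed out
channel-wise, and the result is decimated to the analysis rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .datatypes import MultiTrialRecording, PlatformTrace

__all__ = [
    "OnsetDetectorConfig",
    "EpochSpec",
    "OnsetNotFoundError",
    "detect_onset",
    "segment_epochs",
    "rereference_common_average",
    "correct_ocular",
    "downsample",
]


class OnsetNotFoundError(RuntimeError):
    """Platform displacement never exceeded the detection threshold."""


@dataclass(frozen=True)
class OnsetDetectorConfig:
    """Threshold-crossing onset detector settings.

    ``baseline_window`` seconds immediately preceding each candidate
    sample define the mean and SD of the quiescent oscillation level; the
    first sample deviating by more than ``threshold_sd`` SDs on either
    motion axis is the onset.
    """

    baseline_window: float = 5.0
    threshold_sd: float = 5.0
    directions: tuple[int, ...] = (0, 1)  # medial–lateral, anterior–posterior

    def __post_init__(self) -> None:
        if self.baseline_window <= 0 or self.threshold_sd <= 0:
            raise ValueError("baseline_window and threshold_sd must be positive")


@dataclass(frozen=True)
class EpochSpec:
    """Epoch boundaries relative to the onset (seconds)."""

    pre_onset: float = 3.0
    post_onset: float = 5.0

    def __post_init__(self) -> None:
        if self.pre_onset <= 0 or self.post_onset <= 0:
            raise ValueError("epoch margins must be positive")

    @property
    def length(self) -> float:
        return self.pre_onset + self.post_onset


def detect_onset(trace: PlatformTrace, cfg: OnsetDetectorConfig | None = None) -> int:
    """First sample where platform motion leaves its baseline envelope.

    Returns the first sample index at which the absolute deviation of the
    displacement from the baseline mean exceeds ``threshold_sd`` baseline
    SDs on any checked axis; the baseline statistics are computed over the
    ``baseline_window`` seconds immediately preceding the candidate.

    Raises
    ------
    OnsetNotFoundError
        If no sample crosses the threshold.
    """
    cfg = cfg or OnsetDetectorConfig()
    nb = int(round(cfg.baseline_window * trace.fs))
    disp = trace.displacement[list(cfg.directions)]
    n = disp.shape[1]
    if n <= nb + 1:
        raise ValueError("trace shorter than baseline_window + 1 sample")

    # running baseline mean/SD over the nb samples preceding each candidate
    csum = np.cumsum(disp, axis=1)
    csum2 = np.cumsum(disp**2, axis=1)
    idx = np.arange(nb, n)
    seg_sum = csum[:, idx - 1] - np.concatenate(
        [np.zeros((disp.shape[0], 1)), csum[:, : n - nb - 1]], axis=1
    )
    seg_sum2 = csum2[:, idx - 1] - np.concatenate(
        [np.zeros((disp.shape[0], 1)), csum2[:, : n - nb - 1]], axis=1
    )
    mean = seg_sum / nb
    var = np.maximum(seg_sum2 / nb - mean**2, 0.0)
    sd = np.sqrt(var)
    sd = np.where(sd == 0, np.finfo(float).tiny, sd)

    exceeded = np.abs(disp[:, idx] - mean) > cfg.threshold_sd * sd
    hits = np.flatnonzero(exceeded.any(axis=0))
    if hits.size == 0:
        raise OnsetNotFoundError(
            f"no sample exceeded {cfg.threshold_sd} baseline SDs on any axis"
        )
    return int(idx[hits[0]])


def segment_epochs(
    rec: MultiTrialRecording,
    onsets: np.ndarray,
    spec: EpochSpec | None = None,
) -> MultiTrialRecording:
    """Cut fixed-length epochs around per-trial onsets.

    ``onsets`` has shape ``(n_subjects, n_trials)`` (sample indices into
    each trial).  Trials with insufficient pre/post margin are dropped
    (with a warning); subjects keep a common trial count equal to the
    minimum number of valid trials, so the output stays rectangular.
    """
    spec = spec or EpochSpec()
    pre = int(round(spec.pre_onset * rec.fs))
    post = int(round(spec.post_onset * rec.fs))
    onsets = np.broadcast_to(np.asarray(onsets, int), (rec.n_subjects, rec.n_trials))

    valid = (onsets >= pre) & (onsets + post <= rec.n_samples)
    n_dropped = int((~valid).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} trial(s) with insufficient epoch margin",
            stacklevel=2,
        )
    keep_per_subj = valid.sum(axis=1)
    n_keep = int(keep_per_subj.min())
    if n_keep == 0:
        raise ValueError("no trial has sufficient margin for the requested epoch")

    out = np.empty((rec.n_subjects, n_keep, rec.n_channels, pre + post))
    for s in range(rec.n_subjects):
        kept = np.flatnonzero(valid[s])[:n_keep]
        for k, r in enumerate(kept):
            o = onsets[s, r]
            out[s, k] = rec.data[s, r, :, o - pre : o + post]
    return rec.copy_with(data=out, onset_sample=pre, meta={**rec.meta, "dropped_trials": n_dropped})


def rereference_common_average(
    rec: MultiTrialRecording, eog_channel: str = "EOG"
) -> MultiTrialRecording:
    """Re-reference every EEG channel to the instantaneous EEG mean.

    The EOG channel (if present) is excluded from the average and left
    untouched.  After the transform the across-channel EEG mean is zero
    at every sample.
    """
    eeg = rec.eeg_channel_indices(eog_channel)
    if eeg.size < 2:
        raise ValueError("common average reference requires at least 2 EEG channels")
    data = rec.data.copy()
    avg = data[:, :, eeg, :].mean(axis=2, keepdims=True)
    data[:, :, eeg, :] -= avg
    return rec.copy_with(data=data)


def correct_ocular(
    rec: MultiTrialRecording, eog_channel: str = "EOG", drop_eog: bool = False
) -> MultiTrialRecording:
    """Regression-based (Gratton–Coles style) ocular artifact correction.

    A single blink-propagation coefficient ``b`` per EEG channel is
    estimated by least squares of event-related-average-subtracted EEG on
    event-related-average-subtracted EOG, pooled across all subjects'
    trials; the scaled EOG is then subtracted from the raw channel.
    Subtracting the across-trial average first keeps stimulus-locked
    brain activity out of the propagation estimate.
    """
    ei = rec.channel_index(eog_channel)
    eog = rec.data[:, :, ei, :]  # (S, R, T)
    eeg_idx = rec.eeg_channel_indices(eog_channel)

    eog_res = eog - eog.mean(axis=1, keepdims=True)  # remove event-related average
    denom = float((eog_res**2).sum())
    data = rec.data.copy()
    if denom == 0.0:
        warnings.warn("EOG has zero residual variance; coefficients set to 0", stacklevel=2)
        b = np.zeros(eeg_idx.size)
    else:
        eeg = rec.data[:, :, eeg_idx, :]
        eeg_res = eeg - eeg.mean(axis=1, keepdims=True)
        b = np.einsum("srct,srt->c", eeg_res, eog_res) / denom
    data[:, :, eeg_idx, :] -= b[None, None, :, None] * eog[:, :, None, :]
    meta = {**rec.meta, "ocular_coeffs": dict(zip([rec.channel_names[i] for i in eeg_idx], b))}
    if drop_eog:
        keep = [i for i in range(rec.n_channels) if i != ei]
        return rec.copy_with(
            data=data[:, :, keep, :],
            channel_names=[rec.channel_names[i] for i in keep],
            meta=meta,
        )
    return rec.copy_with(data=data, meta=meta)


def downsample(rec: MultiTrialRecording, factor: int) -> MultiTrialRecording:
    """Decimate by an integer factor with an order-8 Chebyshev-I low-pass.

    The anti-aliasing filter follows the classic decimation convention:
    Chebyshev Type I, order 8, 0.05 dB passband ripple, cutoff at
    0.8 × (fs/2) / factor.  It is applied zero-phase (forward–backward),
    then every ``factor``-th sample is kept.
    """
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if factor == 1:
        return rec
    b, a = signal.cheby1(8, 0.05, 0.8 / factor, output="ba")
    data = signal.filtfilt(b, a, rec.data, axis=-1)
    data = data[..., ::factor]
    onset = rec.onset_sample
    if onset is not None:
        onset = (np.asarray(onset) / factor).astype(int)
        if onset.ndim == 0:
            onset = int(onset)
    return rec.copy_with(data=data, fs=rec.fs / factor, onset_sample=onset)
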