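"""Core in-memory containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["MultiTrialRecording", "PlatformTrace"]


@dataclass
class MultiTrialRecording:
    """Multi-subject, multi-trial, multi-channel EEG-like recording.

    Parameters
    ----------
    data
        Array of shape ``(n_subjects, n_trials, n_channels, n_samples)`` in µV.
    fs
        Sampling rate in Hz.
    channel_names
        One unique label per channel (10:10 system names for scalp channels,
        ``"EOG"`` for the ocular channel).
    onset_sample
        Sample index of the stable→unstable transition, either a scalar
        (same for every trial) or an ``(n_subjects, n_trials)`` array.
    ground_truth
        For synthetic data, the ``SimulationConfig`` that generated it.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    onset_sample: Any = None
    ground_truth: Any = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                "data must be (subjects, trials, channels, samples), got "
                f"ndim={self.data.ndim}"
            )
        if self.data.shape[2] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[2]} channels but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or infinite values")
        if self.onset_sample is not None:
            onset = np.asarray(self.onset_sample)
            if np.any(onset < 0) or np.any(onset >= self.n_samples):
                raise ValueError("onset_sample outside the epoch")

    # -- shape helpers -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def n_samples(self) -> int:
        return self.data.shape[3]

    @property
    def times(self) -> np.ndarray:
        """Epoch-local time axis in seconds (0-based samples)."""
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def eeg_channel_indices(self, eog_channel: str = "EOG") -> np.ndarray:
        """Indices of all non-EOG channels."""
        return np.array(
            [i for i, c in enumerate(self.channel_names) if c != eog_channel]
        )

    def copy_with(self, **kwargs) -> "MultiTrialRecording":
        out = replace(self, **kwargs)
        return out

    def subject(self, i: int) -> "MultiTrialRecording":
        """Single-subject view (subjects axis kept, length 1)."""
        return self.copy_with(data=self.data[i : i + 1].copy())


@dataclass
class PlatformTrace:
    """Platform displacement trace of one 30 s balancing trial.

    ``displacement`` has shape ``(2, n_samples)``: medial–lateral and
    anterior–posterior axes in arbitrary units.  ``true_release_sample`` is
    the sample at which the anchor holding the platform was released.
    """

    displacement: np.ndarray
    fs: float
    true_release_sample: int | None = None

    def __post_init__(self) -> None:
        self.displacement = np.atleast_2d(np.asarray(self.displacement, float))
        if self.displacement.shape[0] != 2:
            raise ValueError("displacement must be (2, n_samples)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement contains non-finite values")
        if self.true_release_sample is not None:
            if not 0 < self.true_release_sample < self.n_samples:
                raise ValueError("release sample must lie strictly inside the trace")

    @property
    def n_samples(self) -> int:
        return self.displacement.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs
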