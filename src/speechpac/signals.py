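"""Shared time-series containers.

Both sides of every coupling in this package are represented by one of two
lightweight containers: :class:`EnvelopeSignal` for the (nonnegative) slow
amplitude envelope of a speech stimulus, and :class:`RoiTimeSeries` for a
neural trace aggregated over a region of interest.  Data are stored as a
2-D array of shape ``(n_trials, n_samples)`` so that spectral estimators can
respect trial boundaries (Welch segments and filter edge trims never cross
a trial boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EnvelopeSignal", "RoiTimeSeries"]


def _as_trials(samples) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 1:
        arr = arr[np.newaxis, :]
    if arr.ndim != 2:
        raise ValueError(f"samples must be 1-D or 2-D, got ndim={arr.ndim}")
    if arr.shape[1] == 0:
        raise ValueError("empty signal (zero samples per trial)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("samples contain non-finite values")
    return arr


@dataclass
class EnvelopeSignal:
    """Wideband amplitude envelope of an acoustic stimulus.

    Parameters
    ----------
    trials : ndarray, shape (n_trials, n_samples)
        Nonnegative envelope samples; a 1-D array is promoted to one trial.
    fs : float
        Sampling rate in Hz.
    condition : str
        Condition label (e.g. ``"normal"``, ``"accelerated"``).
    """

    trials: np.ndarray
    fs: float
    condition: str = "normal"

    def __post_init__(self) -> None:
        self.trials = _as_trials(self.trials)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.min(self.trials) < 0:
            raise ValueError("envelope samples must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[1]

    @property
    def trial_duration(self) -> float:
        """Duration of one trial in seconds."""
        return self.n_samples / self.fs

    @property
    def total_duration(self) -> float:
        return self.n_trials * self.trial_duration

    def times(self) -> np.ndarray:
        """Within-trial time axis in seconds."""
        return np.arange(self.n_samples) / self.fs

    def reversed(self) -> "EnvelopeSignal":
        """Time-reverse each trial (the reversed-stimulus surrogate input)."""
        return replace(self, trials=self.trials[:, ::-1].copy())

    def concatenated(self) -> np.ndarray:
        return self.trials.reshape(-1)


@dataclass
class RoiTimeSeries:
    """Neural time series for one subject x condition x ROI.

    The trace stands in for the voxel-averaged source activity of a region
    of interest (left/right auditory cortex in the motivating design); it
    shares the sampling rate and trial alignment of its paired
    :class:`EnvelopeSignal`.
    """

    trials: np.ndarray
    fs: float
    subject: str = "S01"
    condition: str = "normal"
    roi: str = "LAC"

    def __post_init__(self) -> None:
        self.trials = _as_trials(self.trials)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[1]

    @property
    def total_duration(self) -> float:
        return self.trials.size / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def reversed(self) -> "RoiTimeSeries":
        return replace(self, trials=self.trials[:, ::-1].copy())
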