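"""Narrow-band filtering and analytic-signal machinery.

Shared by the entrainment and phase-amplitude coupling stages: zero-phase
Butterworth band-pass filtering (forward and reverse), and Hilbert-transform
extraction of instantaneous phase and amplitude from a narrow-band signal.

The "fourth-order" band-pass is the order of the low-pass Butterworth
prototype (``scipy.signal.butter(4, [lo, hi], "bandpass")``), applied
forward and reverse, which doubles the effective attenuation and cancels
the phase response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

__all__ = ["BandpassSpec", "AnalyticDynamics", "bandpass", "analytic"]

logger = logging.getLogger(__name__)


@dataclass
class BandpassSpec:
    """One narrow analysis band.

    Parameters
    ----------
    center : float
        Center frequency in Hz.
    halfwidth : float
        Half-bandwidth in Hz; the passband is ``center +/- halfwidth``.
    order : int
        Order of the Butterworth low-pass prototype (even, >= 2).
    zero_phase : bool
        Apply the filter forward and reverse (default), giving zero net
        phase shift.
    """

    center: float
    halfwidth: float = 0.5
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.halfwidth <= 0:
            raise ValueError("halfwidth must be positive")
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be even and >= 2")

    @property
    def lo(self) -> float:
        return self.center - self.halfwidth

    @property
    def hi(self) -> float:
        return self.center + self.halfwidth

    def validate(self, fs: float) -> None:
        if self.lo <= 0:
            raise ValueError(
                f"band {self.lo:.2f}-{self.hi:.2f} Hz touches 0 Hz"
            )
        if self.hi >= fs / 2:
            raise ValueError(
                f"band {self.lo:.2f}-{self.hi:.2f} Hz touches the Nyquist "
                f"frequency ({fs / 2:.2f} Hz)"
            )


@dataclass
class AnalyticDynamics:
    """Instantaneous phase and amplitude of a narrow-band signal.

    ``phase`` is wrapped to (-pi, pi]; ``amplitude`` is nonnegative. Both
    have the same shape as the source signal.
    """

    phase: np.ndarray
    amplitude: np.ndarray
    center: float

    def __post_init__(self) -> None:
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude must share a shape")


@lru_cache(maxsize=4096)
def _design_cached(
    order: int, lo: float, hi: float, fs: float
) -> np.ndarray:
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _design(spec: BandpassSpec, fs: float) -> np.ndarray:
    # comodulograms re-design the same narrow bands thousands of times
    return _design_cached(
        spec.order, round(spec.lo, 9), round(spec.hi, 9), float(fs)
    )


def bandpass(x: np.ndarray, fs: float, spec: BandpassSpec) -> np.ndarray:
    """Zero-phase band-pass filter along the last axis.

    Reflect-padding of about three filter time constants (``3 / halfwidth``
    seconds, capped by the signal length) suppresses edge transients before
    the forward-and-reverse pass.
    """
    x = np.asarray(x, dtype=float)
    spec.validate(fs)
    sos = _design(spec, fs)
    n = x.shape[-1]
    if n < 8:
        raise ValueError("signal too short to filter")
    padlen = int(min(n - 1, round(3 * fs / spec.halfwidth)))
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)
    return sps.sosfilt(sos, x, axis=-1)


def analytic(x_filtered: np.ndarray, center: float) -> AnalyticDynamics:
    """Hilbert phase and amplitude of an (already narrow-band) signal.

    For a pure tone ``A cos(2 pi f t + phi)`` the amplitude is ~A and the
    unwrapped phase advances at ~2 pi f per second away from the edges.
    An all-zero input yields zero amplitude (phase is then meaningless and
    a debug message is logged).
    """
    x_filtered = np.asarray(x_filtered, dtype=float)
    if not np.any(x_filtered):
        logger.debug("analytic(): all-zero input; phase is undefined")
    z = sps.hilbert(x_filtered, axis=-1)
    return AnalyticDynamics(
        phase=np.angle(z), amplitude=np.abs(z), center=center
    )
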