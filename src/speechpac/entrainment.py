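"""Speech-brain coherence spectra, reversed-stimulus surrogates, band peaks.

Coherence is magnitude-squared coherence ``|Sxy|^2 / (Sxx Syy)`` from Welch
cross- and auto-spectra (2 s Hann segments, 50% overlap), evaluated on the
0.5-10 Hz grid at 0.5 Hz resolution.  Segments are taken within trials and
cross-/auto-spectra averaged over all segments of all trials, so the trial
structure of the recording is respected.

The chance level of the estimate is obtained by pairing the neural signal
with the time-reversed stimulus envelope, which preserves the envelope's
spectrum but destroys its temporal alignment with the brain response.

``band_peak`` extracts (Coh_max, f_c): the maximum coherence within a
band of interest and the frequency at which it occurs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
from scipy import signal as sps

from .signals import EnvelopeSignal, RoiTimeSeries

__all__ = [
    "COHERENCE_GRID",
    "DELTA_BANDS",
    "THETA_BANDS",
    "BandDefinition",
    "CoherenceSpectrum",
    "PeakEstimate",
    "coherence_spectrum",
    "surrogate_coherence_spectrum",
    "band_peak",
    "theta_band",
    "delta_band",
]

#: The analysis grid: 0.5 to 10 Hz in 0.5 Hz steps.
COHERENCE_GRID = np.round(np.arange(1, 21) * 0.5, 1)


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band of interest on the coherence grid."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi <= 10:
            raise ValueError(f"invalid band {self.lo}-{self.hi} Hz")


#: Per-condition significant bands reported for this design (overridable).
DELTA_BANDS: Dict[str, BandDefinition] = {
    "decelerated": BandDefinition("delta", 0.5, 2.0),
    "normal": BandDefinition("delta", 0.5, 2.0),
    "accelerated": BandDefinition("delta", 0.5, 2.5),
}
THETA_BANDS: Dict[str, BandDefinition] = {
    "decelerated": BandDefinition("theta", 4.0, 6.5),
    "normal": BandDefinition("theta", 4.5, 7.5),
    "accelerated": BandDefinition("theta", 5.5, 8.5),
}


def theta_band(condition: str) -> BandDefinition:
    """Default theta band of interest for a condition (normal if unknown)."""
    return THETA_BANDS.get(condition, THETA_BANDS["normal"])


def delta_band(condition: str) -> BandDefinition:
    return DELTA_BANDS.get(condition, DELTA_BANDS["normal"])


@dataclass
class CoherenceSpectrum:
    """Coherence values on the 0.5-10 Hz grid for one subject/condition/ROI."""

    freqs: np.ndarray
    coherence: np.ndarray
    subject: str = ""
    condition: str = ""
    roi: str = ""

    def __post_init__(self) -> None:
        if self.freqs.shape != self.coherence.shape:
            raise ValueError("freqs and coherence must share a shape")


@dataclass
class PeakEstimate:
    """(Coh_max, f_c) within a band of interest."""

    peak_value: float
    peak_freq: float
    band: BandDefinition


def _welch_spectra(x: np.ndarray, y: np.ndarray, fs: float):
    """Trial-wise Welch cross/auto spectra averaged over all segments."""
    nperseg = int(round(2.0 * fs))
    noverlap = nperseg // 2
    kw = dict(
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        axis=-1,
    )
    freqs, pxy = sps.csd(x, y, **kw)
    _, pxx = sps.welch(x, **kw)
    _, pyy = sps.welch(y, **kw)
    # equal-length trials contribute equal segment counts: plain mean
    n_seg_per_trial = (x.shape[-1] - noverlap) // (nperseg - noverlap)
    n_segments = int(n_seg_per_trial) * x.shape[0]
    return freqs, pxy.mean(axis=0), pxx.mean(axis=0), pyy.mean(axis=0), n_segments


def coherence_spectrum(
    envelope: EnvelopeSignal, neural: RoiTimeSeries
) -> CoherenceSpectrum:
    """Magnitude-squared coherence between envelope and neural trace.

    Requires matching sampling rates and trial alignment, at least 20 s of
    data in total, and at least 10 Welch segments (fewer make the estimate
    unstable and strongly biased).
    """
    if envelope.fs != neural.fs:
        raise ValueError(
            f"sampling rates differ: envelope {envelope.fs} Hz vs "
            f"neural {neural.fs} Hz"
        )
    if envelope.trials.shape != neural.trials.shape:
        raise ValueError(
            f"trial shapes differ: {envelope.trials.shape} vs "
            f"{neural.trials.shape}"
        )
    if envelope.total_duration < 20.0:
        raise ValueError(
            f"need >= 20 s of data, got {envelope.total_duration:.1f} s"
        )
    freqs, pxy, pxx, pyy, n_segments = _welch_spectra(
        envelope.trials, neural.trials, envelope.fs
    )
    if n_segments < 10:
        raise ValueError(
            f"only {n_segments} Welch segments; need >= 10 for a stable "
            "coherence estimate"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(pxy) ** 2 / (pxx * pyy)
    coh = np.nan_to_num(coh, nan=0.0)
    idx = _grid_indices(freqs)
    return CoherenceSpectrum(
        freqs=COHERENCE_GRID.copy(),
        coherence=np.clip(coh[idx], 0.0, 1.0),
        subject=neural.subject,
        condition=neural.condition,
        roi=neural.roi,
    )


def _grid_indices(freqs: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(freqs, COHERENCE_GRID)
    if not np.allclose(freqs[idx], COHERENCE_GRID, atol=1e-6):
        raise ValueError(
            "Welch grid does not contain the 0.5 Hz analysis frequencies; "
            "is fs a multiple of 0.5 Hz with >= 2 s trials?"
        )
    return idx


def surrogate_coherence_spectrum(
    envelope: EnvelopeSignal, neural: RoiTimeSeries
) -> CoherenceSpectrum:
    """Chance-level coherence: identical estimator, time-reversed envelope.

    Note the degenerate case: an envelope symmetric under time reversal
    (e.g. a pure cosine spanning whole periods) reproduces the real
    coherence exactly.
    """
    return coherence_spectrum(envelope.reversed(), neural)


def band_peak(
    spectrum: CoherenceSpectrum, band: BandDefinition
) -> PeakEstimate:
    """Maximum coherence and its frequency within ``band``.

    Ties are broken toward the lowest frequency.
    """
    mask = (spectrum.freqs >= band.lo - 1e-9) & (
        spectrum.freqs <= band.hi + 1e-9
    )
    if not np.any(mask):
        raise ValueError(
            f"band {band.lo}-{band.hi} Hz contains no grid frequencies"
        )
    freqs = spectrum.freqs[mask]
    values = spectrum.coherence[mask]
    i = int(np.argmax(values))  # first max = lowest frequency on a tie
    return PeakEstimate(
        peak_value=float(values[i]), peak_freq=float(freqs[i]), band=band
    )
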