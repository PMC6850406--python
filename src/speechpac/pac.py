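"""Mutual-information phase-amplitude coupling (PAC) comodulograms.

Coupling between the phase of a slow rhythm and the amplitude of a fast
one is quantified by the mutual information (MI, in bits) between the two
instantaneous dynamics, each discretized into equipopulated bins.  The MI
is estimated by the direct (plug-in) method on the joint histogram and
debiased by quadratic extrapolation: the plug-in estimate is computed on
the full series, on its two halves, and on its four quarters, and the
quadratic trend in inverse sample size is extrapolated to infinite data.

A comodulogram evaluates this estimator on a grid of phase frequencies
(0.5-10 Hz) by amplitude frequencies (10-50 Hz), both in 0.5 Hz steps.
Phase may be taken from the stimulus envelope ("stimulus") or from the
neural signal itself ("neural"); amplitude always comes from the neural
signal.  Chance level is estimated by re-running the estimator with the
time-reversed stimulus (surrogate).

Amplitude filtering bandwidth
-----------------------------
An amplitude band must be wide enough to pass the modulation sidebands at
``f_amp +/- f_phase``, otherwise the filtered amplitude envelope is flat
and carries no coupling information regardless of the true coupling
strength.  The default therefore adapts the amplitude half-bandwidth to
the phase frequency (``f_phase + 1`` Hz, kept clear of the phase band
itself); a fixed half-bandwidth (e.g. the 0.5 Hz used for the phase bands)
can be requested explicitly via :class:`PacConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np

from .signals import EnvelopeSignal, RoiTimeSeries
from .spectral import BandpassSpec, analytic, bandpass

__all__ = [
    "PHASE_GRID",
    "AMP_GRID",
    "BinningSpec",
    "PacConfig",
    "Comodulogram",
    "PacPeak",
    "quantize_equipopulated",
    "mi_plugin",
    "mi_bias_corrected",
    "comodulogram",
    "surrogate_comodulogram",
    "pac_peak",
]

#: Phase-frequency grid: 0.5-10 Hz in 0.5 Hz steps.
PHASE_GRID = np.round(np.arange(1, 21) * 0.5, 1)
#: Amplitude-frequency grid: 10-50 Hz in 0.5 Hz steps.
AMP_GRID = np.round(np.arange(20, 101) * 0.5, 1)


@dataclass(frozen=True)
class BinningSpec:
    """Equipopulated binning with ``n_bins`` quantile bins (10 by default)."""

    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def quantize_equipopulated(
    x: np.ndarray, spec: Union[BinningSpec, int] = BinningSpec()
) -> np.ndarray:
    """Discretize ``x`` into equipopulated bins by empirical quantiles.

    Bin indices run 0..n_bins-1; per-bin counts differ by at most one when
    values are distinct.  Rank ties are resolved by stable order of
    occurrence.  Phase series (circular values in (-pi, pi]) are quantized
    on their numeric value exactly like any other series.
    """
    n_bins = spec.n_bins if isinstance(spec, BinningSpec) else int(spec)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} samples, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) signal")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    # canonical summation order makes MI exactly symmetric in its arguments
    terms = np.sort(p * np.log2(p))
    return -float(np.sum(terms))


def _mi_from_joint(joint: np.ndarray) -> float:
    """MI in bits from a joint count table, as H(X) + H(Y) - H(X, Y).

    Marginals are integer count sums (exact), so the result is bitwise
    identical under argument exchange.
    """
    n = joint.sum()
    return (
        _entropy_bits(joint.sum(axis=1) / n)
        + _entropy_bits(joint.sum(axis=0) / n)
        - _entropy_bits(joint.reshape(-1) / n)
    )


def _joint_counts(
    phase_bins: np.ndarray, amp_bins: np.ndarray, n_bins: int
) -> np.ndarray:
    flat = phase_bins * n_bins + amp_bins
    return np.bincount(flat, minlength=n_bins * n_bins).reshape(
        n_bins, n_bins
    )


def mi_plugin(
    phase_bins: np.ndarray, amp_bins: np.ndarray, n_bins: int = 10
) -> float:
    """Plug-in (direct) MI in bits between two binned series.

    ``MI = sum_ij p(i,j) log2[ p(i,j) / (p(i) p(j)) ]`` over the
    ``n_bins x n_bins`` joint histogram.  Nonnegative and symmetric in its
    arguments.
    """
    phase_bins = np.asarray(phase_bins, dtype=np.int64).ravel()
    amp_bins = np.asarray(amp_bins, dtype=np.int64).ravel()
    if phase_bins.size != amp_bins.size:
        raise ValueError(
            f"length mismatch: {phase_bins.size} vs {amp_bins.size}"
        )
    return _mi_from_joint(_joint_counts(phase_bins, amp_bins, n_bins))


def mi_bias_corrected(
    phase_bins: np.ndarray,
    amp_bins: np.ndarray,
    n_bins: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Quadratic-extrapolation debiased MI in bits.

    Plug-in MI is computed on the full series (N samples), on the two
    contiguous halves (averaged), and on the four contiguous quarters
    (averaged); a quadratic ``MI(v) = a + b v + c v^2`` in the inverse
    sample size ``v in {1/N, 2/N, 4/N}`` is interpolated through the three
    points and its value at v = 0 returned.  Contiguous blocks (rather
    than interleaved samples) preserve the autocorrelation of the
    dynamics within each sub-series.

    The result may be slightly negative on independent data (the plug-in
    bias is subtracted with sampling error).  ``rng`` is reserved for
    randomized sub-sampling schemes and unused by the deterministic block
    scheme.
    """
    phase_bins = np.asarray(phase_bins, dtype=np.int64).ravel()
    amp_bins = np.asarray(amp_bins, dtype=np.int64).ravel()
    if phase_bins.size != amp_bins.size:
        raise ValueError(
            f"length mismatch: {phase_bins.size} vs {amp_bins.size}"
        )
    n = phase_bins.size
    n_min = 40 * n_bins
    if n < n_min:
        raise ValueError(
            f"need at least {n_min} samples for bias correction "
            f"({n_bins} bins), got {n}"
        )
    estimates = []
    inv_sizes = []
    for n_blocks in (1, 2, 4):
        mis = [
            mi_plugin(pb, ab, n_bins)
            for pb, ab in zip(
                np.array_split(phase_bins, n_blocks),
                np.array_split(amp_bins, n_blocks),
            )
        ]
        estimates.append(float(np.mean(mis)))
        inv_sizes.append(n_blocks / n)
    coeffs = np.polyfit(inv_sizes, estimates, 2)
    return float(np.polyval(coeffs, 0.0))


@dataclass
class PacConfig:
    """Grids, filter widths and binning for comodulogram estimation.

    ``amp_halfwidth="auto"`` adapts the amplitude band to each phase
    frequency (half-bandwidth ``f_phase + 1`` Hz, capped so the band stays
    above the phase band and at least 1 Hz wide); a float requests a fixed
    half-bandwidth for every amplitude band.
    """

    phase_freqs: np.ndarray = field(default_factory=lambda: PHASE_GRID.copy())
    amp_freqs: np.ndarray = field(default_factory=lambda: AMP_GRID.copy())
    phase_halfwidth: float = 0.5
    amp_halfwidth: Union[str, float] = "auto"
    n_bins: int = 10
    edge_trim: float = 1.0
    bias_correction: bool = True

    def amp_halfwidth_for(self, f_phase: float, f_amp: float) -> float:
        if isinstance(self.amp_halfwidth, (int, float)):
            return float(self.amp_halfwidth)
        if self.amp_halfwidth != "auto":
            raise ValueError(
                f"amp_halfwidth must be a number or 'auto', "
                f"got {self.amp_halfwidth!r}"
            )
        desired = f_phase + 1.0
        # keep the amplitude band's lower edge above the phase band
        cap = f_amp - (f_phase + 1.5)
        return float(max(1.0, min(desired, cap)))


@dataclass
class Comodulogram:
    """MI matrix over (phase frequency) x (amplitude frequency)."""

    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    mi: np.ndarray  # bits, shape (len(phase_freqs), len(amp_freqs))
    phase_source: str = "stimulus"
    subject: str = ""
    condition: str = ""
    roi: str = ""

    def __post_init__(self) -> None:
        expected = (len(self.phase_freqs), len(self.amp_freqs))
        if self.mi.shape != expected:
            raise ValueError(
                f"mi shape {self.mi.shape} does not match grids {expected}"
            )


@dataclass
class PacPeak:
    """(MI_max, f_phase, f_amp) within a cluster mask."""

    mi_max: float
    f_phase: float
    f_amp: float
    cluster_id: str = ""


def _trimmed_dynamics(
    trials: np.ndarray,
    fs: float,
    spec: BandpassSpec,
    trim: int,
    kind: str,
) -> np.ndarray:
    """Filter all trials, Hilbert, trim edges, concatenate."""
    filtered = bandpass(trials - trials.mean(axis=1, keepdims=True), fs, spec)
    dyn = analytic(filtered, spec.center)
    series = dyn.phase if kind == "phase" else dyn.amplitude
    if trim > 0:
        series = series[:, trim:-trim]
    return series.reshape(-1)


def _phase_trials(
    envelope: EnvelopeSignal,
    neural: RoiTimeSeries,
    phase_source: str,
    reverse_phase: bool,
) -> np.ndarray:
    if phase_source == "stimulus":
        trials = envelope.trials
    elif phase_source == "neural":
        trials = neural.trials
    else:
        raise ValueError(
            f"unknown phase_source {phase_source!r}; "
            "expected 'stimulus' or 'neural'"
        )
    return trials[:, ::-1] if reverse_phase else trials


def _comodulogram_impl(
    envelope: EnvelopeSignal,
    neural: RoiTimeSeries,
    phase_source: str,
    cfg: PacConfig,
    reverse_phase: bool,
) -> Comodulogram:
    if envelope.fs != neural.fs:
        raise ValueError(
            f"sampling rates differ: {envelope.fs} vs {neural.fs} Hz"
        )
    if envelope.trials.shape != neural.trials.shape:
        raise ValueError("envelope and neural trials must be aligned")
    fs = neural.fs
    trim = int(round(cfg.edge_trim * fs))
    if neural.n_samples <= 2 * trim + 8:
        raise ValueError(
            f"trials too short for a {cfg.edge_trim} s edge trim"
        )
    phase_trials = _phase_trials(envelope, neural, phase_source, reverse_phase)

    mi_fn = mi_bias_corrected if cfg.bias_correction else mi_plugin
    n_fp, n_fa = len(cfg.phase_freqs), len(cfg.amp_freqs)
    mi = np.empty((n_fp, n_fa))

    # cache amplitude bins when the bandwidth does not depend on f_phase
    fixed_amp = isinstance(cfg.amp_halfwidth, (int, float))
    amp_bins_cache: Dict[float, np.ndarray] = {}

    for i, fp in enumerate(cfg.phase_freqs):
        # the lowest grid band would touch 0 Hz at full halfwidth; shrink it
        hw_p = min(cfg.phase_halfwidth, 0.8 * float(fp))
        phase_series = _trimmed_dynamics(
            phase_trials,
            fs,
            BandpassSpec(center=float(fp), halfwidth=hw_p),
            trim,
            "phase",
        )
        p_bins = quantize_equipopulated(phase_series, cfg.n_bins)
        for j, fa in enumerate(cfg.amp_freqs):
            key = float(fa)
            if fixed_amp and key in amp_bins_cache:
                a_bins = amp_bins_cache[key]
            else:
                hw = cfg.amp_halfwidth_for(float(fp), float(fa))
                amp_series = _trimmed_dynamics(
                    neural.trials,
                    fs,
                    BandpassSpec(center=float(fa), halfwidth=hw),
                    trim,
                    "amplitude",
                )
                a_bins = quantize_equipopulated(amp_series, cfg.n_bins)
                if fixed_amp:
                    amp_bins_cache[key] = a_bins
            mi[i, j] = mi_fn(p_bins, a_bins, cfg.n_bins)
    return Comodulogram(
        phase_freqs=np.asarray(cfg.phase_freqs, dtype=float),
        amp_freqs=np.asarray(cfg.amp_freqs, dtype=float),
        mi=mi,
        phase_source=phase_source,
        subject=neural.subject,
        condition=neural.condition,
        roi=neural.roi,
    )


def comodulogram(
    envelope: EnvelopeSignal,
    neural: RoiTimeSeries,
    phase_source: str = "stimulus",
    cfg: Optional[PacConfig] = None,
) -> Comodulogram:
    """MI comodulogram between slow phase and fast neural amplitude.

    Phase comes from the stimulus envelope (``phase_source="stimulus"``) or
    from the neural signal (``"neural"``); amplitude always from the neural
    signal.  Per-trial dynamics are concatenated after an edge trim, then
    each cell is the (bias-corrected) MI of the quantized pair.  At least
    ~60 s of data are recommended for a stable debiased estimate.
    """
    return _comodulogram_impl(
        envelope, neural, phase_source, cfg or PacConfig(), reverse_phase=False
    )


def surrogate_comodulogram(
    envelope: EnvelopeSignal,
    neural: RoiTimeSeries,
    phase_source: str = "stimulus",
    cfg: Optional[PacConfig] = None,
) -> Comodulogram:
    """Chance-level comodulogram from the time-reversed stimulus.

    For ``phase_source="stimulus"`` the envelope is time-reversed per
    trial; for ``"neural"`` the neural phase series is time-reversed
    relative to the (unreversed) amplitude series.  Marginal distributions
    are preserved; temporal alignment between phase and amplitude is
    destroyed.  Applying the reversal twice reproduces the real
    comodulogram.
    """
    cfg = cfg or PacConfig()
    if phase_source == "stimulus":
        return _comodulogram_impl(
            envelope.reversed(), neural, phase_source, cfg, reverse_phase=False
        )
    return _comodulogram_impl(
        envelope, neural, phase_source, cfg, reverse_phase=True
    )


def pac_peak(
    comod: Comodulogram, cluster_mask: Optional[np.ndarray] = None
) -> PacPeak:
    """Maximum MI within a cluster mask and its grid coordinates.

    ``cluster_mask=None`` searches the whole matrix.  Ties break toward
    the lowest phase frequency, then the lowest amplitude frequency.
    """
    if cluster_mask is None:
        cluster_mask = np.ones_like(comod.mi, dtype=bool)
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if cluster_mask.shape != comod.mi.shape:
        raise ValueError("cluster mask shape does not match the comodulogram")
    if not cluster_mask.any():
        raise ValueError("no significant cluster")
    masked = np.where(cluster_mask, comod.mi, -np.inf)
    # row-major argmax: first occurrence = lowest f_phase, then lowest f_amp
    i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
    return PacPeak(
        mi_max=float(comod.mi[i, j]),
        f_phase=float(comod.phase_freqs[i]),
        f_amp=float(comod.amp_freqs[j]),
    )
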