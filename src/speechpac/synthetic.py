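"""Synthetic cohorts with known entrainment and coupling ground truth.

Every downstream stage of the pipeline (envelope spectra, speech-brain
coherence, theta-gamma comodulograms, group statistics) is exercised on
cohorts produced here, where the syllabic rate, prosodic rate, gamma
carrier, coupling depth, and tempo factor are known exactly.

The stimulus envelope is a quasi-periodic pulse train: one raised-cosine
pulse per syllable, pulse times jittered by a fraction of the syllabic
period, multiplied by a slow prosodic modulation.  Its power spectrum shows
two peaks, one at the prosodic (delta) rate and one at the syllabic (theta)
rate, as natural-speech envelopes do.

The neural trace is built from the envelope:

``x(t) = entrainment_strength * cos(phi_env(t) - phase_lag) + g(t) + noise``

where ``phi_env`` is the Hilbert phase of the envelope around the
(tempo-scaled) syllable rate -- so the theta component is phase-locked to
the stimulus -- and

``g(t) = a * (1 + m * cos(phi_theta(t) - phi0)) * cos(2 pi f_gamma t + psi)``

is a gamma carrier whose amplitude is modulated by theta phase with depth
``m = coupling_depth``.  Background noise is spectrally shaped Gaussian
noise (power ~ 1/f^exponent) scaled so that the RMS ratio of the
oscillatory part to the noise equals ``snr``.

Tempo manipulation is a uniform time-axis rescale of the envelope (duration
divided by the factor, sampling rate unchanged), after which the neural
generator scales the gamma carrier by the same factor; this mirrors a
pitch-preserving tempo change of the source audio at the envelope level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
from scipy import signal as sps

from .signals import EnvelopeSignal, RoiTimeSeries
from .spectral import BandpassSpec, analytic, bandpass

__all__ = [
    "SyntheticCohortConfig",
    "Cohort",
    "CohortEntry",
    "generate_envelope",
    "apply_tempo",
    "generate_neural",
    "generate_cohort",
    "one_over_f_noise",
]


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the motivating design: ~10 s sentences at a 5.5 Hz
    syllabic rate with a slow prosodic modulation, a gamma carrier at 33 Hz
    whose amplitude is coupled to theta phase, and tempo conditions at
    factors 0.75 / 1.0 / 1.25 of the normal rate.

    Parameters
    ----------
    n_subjects : int
        Cohort size.
    fs : float
        Sampling rate of envelope and neural traces, Hz.  All analysis
        bands lie below 50 Hz, so 200 Hz is ample; set 1000.0 to mimic raw
        acquisition rates.
    trial_duration : float
        Seconds per trial ("sentence") before tempo scaling.
    n_trials : int
        Trials per subject and condition.
    syllable_rate, prosodic_rate : float
        Ground-truth theta and delta rhythms of the envelope, Hz.
    gamma_freq : float
        Ground-truth amplitude carrier, Hz (before tempo scaling).
    coupling_depth : float
        Modulation depth m of the gamma amplitude by theta phase, in [0, 1].
    entrainment_strength : float
        Amplitude of the envelope-locked theta component (>= 0).
    phase_lag : float
        Phase lag phi0 (radians) of theta relative to the envelope, also
        used as the coupling phase of the gamma modulation.
    noise_exponent : float
        Spectral slope of the background noise (power ~ 1/f^exponent).
    snr : float
        RMS ratio of the oscillatory part (theta + gamma) to the noise.
    tempo_factors : dict
        Condition label -> positive tempo factor; must map "normal" to 1.0.
    rois : tuple of str
        ROI labels; each gets an independent noise realization.
    subject_rate_sd, subject_gamma_sd : float
        Between-subject SD of syllable_rate (Hz) and gamma_freq (Hz).
    prosodic_depth : float
        Depth of the slow prosodic modulation of the pulse train, in [0, 1).
    pulse_jitter_frac : float
        SD of the pulse-time jitter as a fraction of the syllabic period
        (truncated at 4 SD to keep pulse order).
    gamma_amplitude : float
        Mean amplitude a of the gamma carrier relative to the unit theta
        component.
    seed : int
        Root seed; all randomness derives from it deterministically.
    """

    n_subjects: int = 10
    fs: float = 200.0
    trial_duration: float = 10.0
    n_trials: int = 6
    syllable_rate: float = 5.5
    prosodic_rate: float = 1.8
    gamma_freq: float = 33.0
    coupling_depth: float = 0.7
    entrainment_strength: float = 1.0
    phase_lag: float = 0.0
    noise_exponent: float = 1.0
    snr: float = 1.0
    tempo_factors: Dict[str, float] = field(
        default_factory=lambda: {
            "decelerated": 0.75,
            "normal": 1.0,
            "accelerated": 1.25,
        }
    )
    rois: Tuple[str, ...] = ("LAC", "RAC")
    subject_rate_sd: float = 0.25
    subject_gamma_sd: float = 1.5
    prosodic_depth: float = 0.5
    pulse_jitter_frac: float = 0.10
    gamma_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.fs < 4 * self.gamma_freq:
            raise ValueError(
                f"fs={self.fs} Hz too low for gamma_freq={self.gamma_freq} Hz "
                "(need fs >= 4 x gamma_freq)"
            )
        if not 0.0 <= self.coupling_depth <= 1.0:
            raise ValueError("coupling_depth must lie in [0, 1]")
        if self.entrainment_strength < 0:
            raise ValueError("entrainment_strength must be >= 0")
        if self.tempo_factors.get("normal") != 1.0:
            raise ValueError('tempo_factors must map "normal" to 1.0')
        if any(f <= 0 for f in self.tempo_factors.values()):
            raise ValueError("tempo factors must be positive")
        fmax = max(self.tempo_factors.values())
        for name, rate in [
            ("syllable_rate", self.syllable_rate),
            ("prosodic_rate", self.prosodic_rate),
            ("gamma_freq", self.gamma_freq),
        ]:
            if rate <= 0 or rate * fmax >= self.fs / 2:
                raise ValueError(
                    f"{name}={rate} Hz out of range for fs={self.fs} Hz"
                )
        if not 0.0 <= self.prosodic_depth < 1.0:
            raise ValueError("prosodic_depth must lie in [0, 1)")
        if self.n_trials < 1 or self.trial_duration <= 0:
            raise ValueError("need n_trials >= 1 and trial_duration > 0")


def one_over_f_noise(
    n: int, exponent: float, rng: np.random.Generator, fs: float = 1.0
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pulse_train_trial(
    config: SyntheticCohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """One trial of the base (normal-tempo) envelope."""
    fs = config.fs
    n = int(round(config.trial_duration * fs))
    t = np.arange(n) / fs
    period = 1.0 / config.syllable_rate
    # quasi-rhythmic syllable onsets: i.i.d. inter-pulse intervals with SD
    # = pulse_jitter_frac of the period (truncated to keep pulse order), so
    # pulse timing drifts cumulatively as natural syllable trains do and
    # the stimulus phase decorrelates over a trial (grid-anchored jitter
    # would leave the time-reversed stimulus nearly as coherent with the
    # brain signal as the real one)
    jitter_sd = config.pulse_jitter_frac * period
    n_pulses = int(np.ceil(config.trial_duration / period * 1.5)) + 3
    intervals = period + np.clip(
        rng.normal(0.0, jitter_sd, size=n_pulses), -0.4 * period, 0.4 * period
    )
    times = rng.uniform(0.0, period) + np.cumsum(intervals) - intervals[0] / 2
    times = times[times < config.trial_duration]
    impulses = np.zeros(n)
    idx = np.round(times * fs).astype(int)
    valid = (idx >= 0) & (idx < n)
    np.add.at(impulses, idx[valid], 1.0)
    # raised-cosine (Hann) pulse spanning ~60% of the syllabic period
    klen = max(3, int(round(0.6 * period * fs)))
    kernel = np.hanning(klen + 2)[1:-1]
    pulses = sps.fftconvolve(impulses, kernel, mode="same")
    pulses = np.clip(pulses, 0.0, None)  # fftconvolve round-off
    phi_p = rng.uniform(0.0, 2 * np.pi)
    prosody = 1.0 + config.prosodic_depth * np.cos(
        2 * np.pi * config.prosodic_rate * t + phi_p
    )
    return pulses * prosody


def generate_envelope(
    config: SyntheticCohortConfig,
    condition: str,
    rng: np.random.Generator | None = None,
) -> EnvelopeSignal:
    """Generate the stimulus envelope for one subject and condition.

    The base (normal-tempo) pulse train is generated first and then
    tempo-scaled by the condition's factor, mirroring how rate-manipulated
    stimuli are derived from the normal recordings.
    """
    if condition not in config.tempo_factors:
        raise ValueError(
            f"unknown condition {condition!r}; known: "
            f"{sorted(config.tempo_factors)}"
        )
    if config.fs < 4 * config.syllable_rate:
        raise ValueError(
            f"fs={config.fs} Hz too low for syllable_rate="
            f"{config.syllable_rate} Hz"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    trials = np.stack(
        [_pulse_train_trial(config, rng) for _ in range(config.n_trials)]
    )
    base = EnvelopeSignal(trials=trials, fs=config.fs, condition=condition)
    return apply_tempo(base, config.tempo_factors[condition])


def apply_tempo(envelope: EnvelopeSignal, factor: float) -> EnvelopeSignal:
    """Uniform time-axis rescale of the envelope (pitch-neutral tempo change).

    The output lasts ``duration / factor`` at the unchanged sampling rate,
    so every spectral peak frequency is multiplied by ``factor``.
    """
    if factor <= 0:
        raise ValueError(f"tempo factor must be positive, got {factor}")
    if factor == 1.0:
        return replace(envelope, trials=envelope.trials.copy())
    n_in = envelope.n_samples
    n_out = int(round(n_in / factor))
    if n_out < 2:
        raise ValueError("tempo factor collapses the trial below 2 samples")
    t_in = np.arange(n_in) / envelope.fs
    t_out = np.arange(n_out) / envelope.fs * factor
    out = np.stack(
        [np.interp(t_out, t_in, trial) for trial in envelope.trials]
    )
    return replace(envelope, trials=out)


def generate_neural(
    envelope: EnvelopeSignal,
    config: SyntheticCohortConfig,
    rng: np.random.Generator | None = None,
    subject: str = "S01",
    roi: str = "LAC",
) -> RoiTimeSeries:
    """Simulate one ROI trace entrained and coupled to the given envelope.

    See the module docstring for the generative model.  The condition's
    tempo factor (looked up from ``envelope.condition``) scales both the
    theta tracking band and the gamma carrier.
    """
    if config.snr <= 0:
        raise ValueError(f"snr must be positive, got {config.snr}")
    if envelope.fs != config.fs:
        raise ValueError(
            f"envelope fs={envelope.fs} does not match config fs={config.fs}"
        )
    if envelope.condition not in config.tempo_factors:
        raise ValueError(f"unknown condition {envelope.condition!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    factor = config.tempo_factors[envelope.condition]
    rate = config.syllable_rate * factor
    f_gamma = config.gamma_freq * factor
    fs = config.fs
    n = envelope.n_samples
    t = np.arange(n) / fs

    halfwidth = min(1.0, 0.45 * rate)  # keep the tracking band above 0 Hz
    spec = BandpassSpec(center=rate, halfwidth=halfwidth)
    out = np.empty_like(envelope.trials)
    for k, env_trial in enumerate(envelope.trials):
        narrow = bandpass(env_trial - env_trial.mean(), fs, spec)
        phi_env = analytic(narrow, rate).phase
        phi_theta = phi_env - config.phase_lag
        theta = np.cos(phi_theta)
        psi = rng.uniform(0.0, 2 * np.pi)
        gamma = (
            config.gamma_amplitude
            * (1.0 + config.coupling_depth * np.cos(phi_theta - config.phase_lag))
            * np.cos(2 * np.pi * f_gamma * t + psi)
        )
        osc = config.entrainment_strength * theta + gamma
        noise = one_over_f_noise(n, config.noise_exponent, rng, fs=fs)
        osc_rms = np.sqrt(np.mean(osc**2))
        out[k] = osc + noise * (osc_rms / config.snr if osc_rms > 0 else 1.0)
    return RoiTimeSeries(
        trials=out,
        fs=fs,
        subject=subject,
        condition=envelope.condition,
        roi=roi,
    )


@dataclass
class CohortEntry:
    """Stimulus envelope plus per-ROI neural traces for one subject x condition."""

    subject: str
    condition: str
    envelope: EnvelopeSignal
    neural: Dict[str, RoiTimeSeries]


@dataclass
class Cohort:
    """A full synthetic cohort with its ground truth.

    ``ground_truth[subject]`` records the subject's jittered syllabic rate
    and gamma carrier (at normal tempo); multiply by the condition's tempo
    factor for condition-specific truth.
    """

    config: SyntheticCohortConfig
    entries: List[CohortEntry]
    ground_truth: Dict[str, Dict[str, float]]

    @property
    def subjects(self) -> List[str]:
        return sorted({e.subject for e in self.entries})

    @property
    def conditions(self) -> List[str]:
        return list(self.config.tempo_factors)

    def get(self, subject: str, condition: str) -> CohortEntry:
        for e in self.entries:
            if e.subject == subject and e.condition == condition:
                return e
        raise KeyError(f"no entry for subject={subject!r}, condition={condition!r}")


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Generate ``n_subjects x |tempo_factors| x |rois|`` coupled signal pairs.

    Per-subject random streams derive deterministically from ``config.seed``
    via :class:`numpy.random.SeedSequence` spawning, so an identical config
    reproduces a bitwise-identical cohort across process invocations.
    Between-subject variability enters through Gaussian jitter of the
    syllabic rate and gamma carrier (SDs from the config); within a subject
    the same base envelope underlies every tempo condition, as when one set
    of sentences is re-rendered at several speeds.
    """
    root = np.random.SeedSequence(config.seed)
    subject_seqs = root.spawn(config.n_subjects)
    entries: List[CohortEntry] = []
    ground_truth: Dict[str, Dict[str, float]] = {}
    for i, seq in enumerate(subject_seqs):
        subject = f"S{i + 1:02d}"
        jit_seq, env_seq, *noise_seqs = seq.spawn(
            2 + len(config.tempo_factors) * len(config.rois)
        )
        jit_rng = np.random.default_rng(jit_seq)
        rate_i = config.syllable_rate + jit_rng.normal(0, config.subject_rate_sd)
        gamma_i = config.gamma_freq + jit_rng.normal(0, config.subject_gamma_sd)
        # guard rails: jitter must not push rates into degenerate ranges
        rate_i = float(np.clip(rate_i, 1.0, config.fs / 8))
        gamma_i = float(np.clip(gamma_i, 4 * rate_i, config.fs / 4))
        cfg_i = replace(
            config, syllable_rate=rate_i, gamma_freq=gamma_i, n_subjects=1
        )
        ground_truth[subject] = {
            "syllable_rate": rate_i,
            "gamma_freq": gamma_i,
        }
        env_state = env_seq.entropy
        k = 0
        for condition in config.tempo_factors:
            # identical base envelope across conditions: fresh rng per call
            env_rng = np.random.default_rng(np.random.SeedSequence(env_state))
            env = generate_envelope(cfg_i, condition, env_rng)
            neural: Dict[str, RoiTimeSeries] = {}
            for roi in config.rois:
                roi_rng = np.random.default_rng(noise_seqs[k])
                k += 1
                neural[roi] = generate_neural(
                    env, cfg_i, roi_rng, subject=subject, roi=roi
                )
            entries.append(
                CohortEntry(
                    subject=subject,
                    condition=condition,
                    envelope=env,
                    neural=neural,
                )
            )
    return Cohort(config=config, entries=entries, ground_truth=ground_truth)
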