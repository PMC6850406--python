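# Methods

`speechpac` analyzes how cortical oscillations track the rhythm of speech
at two levels: low-frequency entrainment of auditory-cortex activity to
the speech envelope, and cross-frequency coupling in which the phase of
the theta rhythm modulates the amplitude of gamma activity.  Because no
public dataset accompanies the motivating design, every analysis stage is
validated on synthetic cohorts with known ground truth; this note records
the models, defaults, and numerical choices, and what the synthetic
validation does and does not establish.

## Synthetic cohort model

**Stimulus envelope.**  One trial ("sentence") is a quasi-periodic pulse
train: one raised-cosine (Hann) pulse per syllable, spanning ~60% of the
syllabic period.  Inter-pulse intervals are i.i.d. Gaussian around the
syllabic period with SD equal to `pulse_jitter_frac` (default 0.10) of the
period, truncated at ±40% to preserve pulse order.  Jittering the
*intervals* (rather than pulse times around a fixed grid) makes pulse
timing drift cumulatively, as natural syllable trains do; this matters for
the surrogate analysis, because a phase-deterministic stimulus would remain
almost as coherent with the brain signal after time reversal as before it.
The train is multiplied by `1 + prosodic_depth * cos(2 pi f_prosodic t +
phi)` (depth 0.5, random phase per trial), producing the two-peaked power
spectrum characteristic of speech envelopes: a prosodic (delta) peak at
`prosodic_rate` (default 1.8 Hz) and a syllabic (theta) peak at
`syllable_rate` (default 5.5 Hz).

**Tempo manipulation.**  A tempo change is a uniform rescale of the
envelope's time axis: the trial is resampled (linear interpolation) to
`duration / factor` at the unchanged sampling rate, multiplying every
spectral peak frequency by the factor.  This is the envelope-level
equivalent of a pitch-preserving tempo change of the source audio, which
is the pipeline's unit of analysis.  Conditions default to factors 0.75
(decelerated), 1.0 (normal), and 1.25 (accelerated), and all conditions of
one subject re-render the same base envelope, as when one sentence set is
produced at several speeds.

**Neural trace.**  Per ROI,

```
x(t) = E * cos(phi_env(t) - phi0)                                # theta
     + a * (1 + m * cos(phi_theta(t) - phi0)) * cos(2 pi f_g t)  # gamma
     + noise(t)                                                  # 1/f
```

where `phi_env` is the Hilbert phase of the envelope band-passed around
the (tempo-scaled) syllabic rate, so the theta component is genuinely
phase-locked to the stimulus; `E = entrainment_strength` (default 1);
`m = coupling_depth` (default 0.7) sets the depth of theta-phase
modulation of the gamma amplitude; `a = gamma_amplitude` (default 0.5)
and `f_g = gamma_freq x tempo factor` (default 33 Hz at normal tempo);
`phi0 = phase_lag` (default 0).  The noise is spectrally shaped Gaussian
noise with power ~ 1/f (exponent configurable), scaled so the RMS ratio of
the oscillatory part to the noise equals `snr` (default 1).

**Cohort structure.**  Subjects receive Gaussian jitter of the syllabic
rate (SD 0.25 Hz) and gamma carrier (SD 1.5 Hz), giving group-level
dispersion comparable to published between-subject spreads of theta and
gamma peak values.  All randomness derives from one root seed via
`numpy.random.SeedSequence` spawning, so an identical config reproduces a
bitwise-identical cohort across processes.  Defaults: 10 subjects, 6
trials of 10 s each (60 s per subject per condition), 2 ROIs.

**Sampling rate.**  Traces are generated at 200 Hz.  Every analysis band
lies at or below 50 Hz, so 200 Hz loses nothing relative to a 1 kHz
acquisition rate; a config switch restores 1 kHz for users who want
acquisition-scale data.

**What the generator does not emulate.**  There is no phonemic or
articulatory structure, no sentence-to-sentence variation in duration, no
sensor-level physics, no eye-blink or cardiac artifacts, and no evoked
(non-oscillatory) responses.  The coupling is stationary within a trial,
whereas real theta–gamma coupling fluctuates with acoustic landmarks.
Passing tests therefore establish estimator correctness and parameter
recovery under a favorable, stationary generative model — not performance
on real M/EEG recordings.

## Envelope extraction

Audio is passed through a bank of 24 gammatone filters (`scipy.signal.
gammatone`) with centers ERB-spaced from 100 to 4000 Hz (conventional
values for cochlear-model envelope work; the channel count mainly trades
smoothness for compute).  Channel envelopes are magnitudes of the analytic
signal, **averaged** (not summed) across channels so the amplitude scale
is independent of the channel count, low-pass filtered below half the
output rate, and resampled to the analysis rate.  Envelope power spectra
use Welch averaging with 2 s Hann windows and 50% overlap, which realizes
a 0.5 Hz frequency grid.

## Narrow-band filtering and analytic dynamics

All narrow bands use a Butterworth band-pass of prototype order 4 applied
forward and reverse (`sosfiltfilt`), i.e. zero net phase and doubled
attenuation.  Signals are reflect-padded by about three filter time
constants (`3 / halfwidth` seconds, capped by the trial length) to
suppress edge transients.  Phase and amplitude are the angle and magnitude
of the Hilbert analytic signal.  Per-trial filtering with a 1 s edge trim,
followed by concatenation of the dynamics, keeps filter transients out of
the phase estimates.

## Coherence

Magnitude-squared coherence `|Sxy|^2 / (Sxx Syy)` from Welch cross- and
auto-spectra (2 s Hann, 50% overlap), segments taken within trials and
averaged over all segments, evaluated on the 0.5–10 Hz grid at 0.5 Hz
steps.  At least 20 s of data and 10 segments are required.  For
independent signals the expectation is ~`1/K` for `K` segments; 50%
Hann overlap correlates adjacent segments and inflates this by
`(1 + 2 c^2) ~ 5%`, where `c ~ 0.163` is the normalized overlap of
shifted Hann windows — the tolerance used in the chance-level tests
allows for this.  Chance level in the analysis itself is estimated by
pairing the brain signal with the time-reversed envelope (per trial),
which preserves the envelope's spectrum while destroying temporal
alignment.  Band peaks (Coh_max, f_c) are grid argmaxima within a band of
interest, ties broken toward the lowest frequency; default bands are the
per-condition delta/theta ranges of the motivating design and are
config-overridable.

## Mutual-information comodulograms

Phase dynamics are computed on the 0.5–10 Hz grid (±0.5 Hz bands) from
the stimulus envelope or from the neural signal — both modes are
first-class, since speech-phase x neural-amplitude and neural-phase x
neural-amplitude coupling are both meaningful and, on strongly entrained
signals, nearly interchangeable (the entrained theta carries the stimulus
phase).  Amplitude dynamics come from the neural signal on the 10–50 Hz
grid.

**Amplitude bandwidth.**  A band-pass around an amplitude carrier only
transmits amplitude modulation at rates below its half-bandwidth: the
modulation lives in sidebands at `f_amp ± f_phase`.  A fixed ±0.5 Hz
amplitude band therefore cannot carry theta-rate modulation at all — the
filtered amplitude is flat and the comodulogram is structurally blind,
regardless of the true coupling.  The default is consequently adaptive:
half-bandwidth `f_phase + 1` Hz, capped so the amplitude band's lower edge
stays above the phase band (and at least 1 Hz).  With this choice the MI
peak localizes at the true carrier: only bands centered within about
±1 Hz of the carrier contain the carrier plus both sidebands.  A fixed
half-bandwidth (including the ±0.5 Hz setting that mirrors the phase
bands) remains available via `PacConfig(amp_halfwidth=...)` for
sensitivity analyses.  The lowest phase band (0.5 Hz center) is shrunk to
80% of its center so it cannot touch 0 Hz.

**MI estimation.**  Phase and amplitude series are each discretized into
10 equipopulated bins by empirical quantiles (rank-based; ties resolved by
order of occurrence; per-bin counts differ by at most one).  Phase is
binned on its numeric value in (-pi, pi] exactly like any other series.
Plug-in MI is `H(X) + H(Y) - H(X, Y)` over the 10x10 joint histogram, in
bits, computed with integer marginal counts and canonically ordered
summation so that `MI(a, b)` equals `MI(b, a)` bitwise.  Bias is removed
by quadratic extrapolation: plug-in MI on the full series, the mean over
its two halves, and the mean over its four quarters define three points
`MI(v)` at inverse sample sizes `v = 1/N, 2/N, 4/N`; the interpolating
quadratic evaluated at `v = 0` is the estimate.  Contiguous blocks (not
interleaved samples) preserve the autocorrelation of the dynamics within
each sub-series.  The corrected estimate can be slightly negative on
independent data; on 10^4-sample independent series the plug-in bias
~`(B-1)^2 / (2 N ln 2)` ~ 0.006 bits is removed to below 0.01 bits.
Bias correction requires at least 40 samples per bin.

**Surrogates.**  The stimulus-phase surrogate recomputes the comodulogram
with the per-trial time-reversed envelope; the neural-phase surrogate
time-reverses the neural phase series relative to the (unreversed)
amplitude series.  Reversal is an involution: applied twice it reproduces
the real comodulogram exactly.

**Peaks.**  (MI_max, f_phase, f_amp) is the argmax of MI restricted to a
cluster mask, ties toward the lowest phase then amplitude frequency.  In
the pipeline the mask is the significant positive cluster; if none exists
for a condition the whole matrix is searched and the row flagged
`global`, so summary tables keep every condition.

## Group statistics

Real and surrogate values are compared within subject by a two-tailed
cluster-based permutation test: per-bin paired t statistics of
(real − surrogate); cluster-forming threshold at two-sided p = 0.05 on
the t distribution with n−1 degrees of freedom (configurable; the
procedure's threshold is not dictated by the method itself); clusters by
contiguity in 1-D and 4-connectivity in 2-D (8 available); cluster
statistic = sum of t within the cluster; null distribution = maximum
absolute cluster statistic over random per-subject sign flips of the
differences (the appropriate exchangeability scheme for a paired design);
cluster p = `(1 + #{null >= observed}) / (n_perm + 1)`, 1000 permutations
by default.  At least 5 subjects are required (the sign-flip null has
2^n states).  On null simulations the family-wise error is ~0.05; the
implementation is cross-checked in the test suite against MNE-Python's
cluster permutation test on identical inputs.  p-values are invariant to
subject reordering up to permutation-sampling noise; the observed cluster
statistics are exactly invariant.

## Pipeline and reproducibility

`run_all` chains simulate → envelope → entrain → PAC → stats → report,
writing TSV/JSON artifacts per stage and a run manifest (config hash,
seed, version, per-stage file listing, timestamps).  Result tables are
deterministic under a fixed config; peaks tables carry one row per
subject x condition x ROI (x band), and summaries report group mean and
standard error `SD/sqrt(n)` in a `mean(SE)` layout, plus an ordering
summary of f_c, f_phase, and f_amp group means against the tempo factor.
Repeated-measures ANOVAs and normality checks on the peak tables are
deliberately out of scope — the tables are written in the tidy format
those routine tests consume.

## Problem sizes used in validation

The test suite exercises the estimators at desk scale: cohorts of 5–10
subjects with 30–60 s per subject per condition for coherence and PAC
recovery, 20 seeded replicates for comodulogram argmax recovery, 100–200
Monte-Carlo replicates for the MI-bias and permutation-validity checks
(500 permutations), and 50 subjects for the surrogate null sign test.
These sizes make the checks statistically meaningful while keeping the
full suite in the minutes range; all scale up linearly via the config.

## Known limitations

- Reversed-stimulus surrogates under-estimate chance level for stimuli
  that are symmetric or strongly periodic; the generator avoids this by
  construction, but user-supplied rhythmic stimuli may not.
- The adaptive amplitude bandwidth couples the amplitude-axis resolution
  to the phase frequency; MI values are comparable within a comodulogram
  row, and across rows only qualitatively.
- The quadratic-extrapolation debiasing assumes the bias is smooth in
  inverse sample size; for strongly autocorrelated dynamics the effective
  sample size is smaller than N and residual bias remains.
- Coherence and MI are computed per ROI trace; voxel-level aggregation
  (averaging estimates over traces) is the caller's responsibility when
  more than one trace per ROI is supplied.
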