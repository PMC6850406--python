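"""Synthetic cohort generator: spectral ground truth, tempo, determinism."""

import dataclasses

import numpy as np
import pytest

from speechpac.envelope import envelope_power_spectrum
from speechpac.synthetic import (
    SyntheticCohortConfig,
    apply_tempo,
    generate_cohort,
    generate_envelope,
    generate_neural,
    one_over_f_noise,
)


def _band_argmax(spec, lo, hi):
    m = (spec.freqs >= lo) & (spec.freqs <= hi)
    return spec.freqs[m][np.argmax(spec.power[m])]


class TestGenerateEnvelope:
    def test_nonnegative_and_finite(self, base_config):
        env = generate_envelope(base_config, "normal", np.random.default_rng(0))
        assert np.min(env.trials) >= 0
        assert np.all(np.isfinite(env.trials))

    def test_syllabic_spectral_peak(self, base_config):
        env = generate_envelope(base_config, "normal", np.random.default_rng(1))
        spec = envelope_power_spectrum(env)
        assert _band_argmax(spec, 4.0, 8.0) == pytest.approx(5.5, abs=0.5)

    def test_prosodic_and_syllabic_local_maxima(self, base_config):
        """The envelope spectrum shows a delta peak and a theta peak."""
        env = generate_envelope(base_config, "normal", np.random.default_rng(2))
        spec = envelope_power_spectrum(env)
        assert abs(_band_argmax(spec, 0.5, 3.0) - base_config.prosodic_rate) <= 1.0
        assert abs(_band_argmax(spec, 4.0, 7.0) - base_config.syllable_rate) <= 1.0

    def test_seeded_determinism(self, base_config):
        a = generate_envelope(base_config, "normal", np.random.default_rng(3))
        b = generate_envelope(base_config, "normal", np.random.default_rng(3))
        np.testing.assert_array_equal(a.trials, b.trials)

    def test_unknown_condition_names_label(self, base_config):
        with pytest.raises(ValueError, match="warp"):
            generate_envelope(base_config, "warp", np.random.default_rng(0))

    def test_fs_too_low_for_syllable_rate(self):
        cfg = SyntheticCohortConfig(fs=200.0)
        low = dataclasses.replace(cfg, fs=150.0, gamma_freq=30.0,
                                  syllable_rate=40.0)
        with pytest.raises(ValueError):
            generate_envelope(low, "normal", np.random.default_rng(0))


class TestApplyTempo:
    def test_identity(self, base_config):
        env = generate_envelope(base_config, "normal", np.random.default_rng(4))
        out = apply_tempo(env, 1.0)
        np.testing.assert_array_equal(out.trials, env.trials)

    @pytest.mark.parametrize("factor", [1.25, 0.75])
    def test_peak_scales_with_factor(self, base_config, factor):
        env = generate_envelope(base_config, "normal", np.random.default_rng(5))
        scaled = apply_tempo(env, factor)
        spec = envelope_power_spectrum(scaled)
        lo, hi = 5.5 * factor - 1.5, 5.5 * factor + 1.5
        assert _band_argmax(spec, lo, hi) == pytest.approx(
            5.5 * factor, abs=0.5
        )

    def test_duration_scales(self, base_config):
        env = generate_envelope(base_config, "normal", np.random.default_rng(6))
        out = apply_tempo(env, 1.25)
        assert out.n_samples == round(env.n_samples / 1.25)

    def test_composition(self, base_config):
        """Tempo scaling is multiplicative up to resampling error."""
        env = generate_envelope(base_config, "normal", np.random.default_rng(7))
        twice = apply_tempo(apply_tempo(env, 1.25), 0.8)
        once = apply_tempo(env, 1.0)  # 1.25 * 0.8
        n = min(twice.n_samples, once.n_samples)
        err = np.max(np.abs(twice.trials[:, :n] - once.trials[:, :n]))
        assert err < 0.05 * np.max(env.trials)

    @pytest.mark.parametrize("factor", [0.0, -1.0])
    def test_invalid_factor(self, base_config, factor):
        env = generate_envelope(base_config, "normal", np.random.default_rng(8))
        with pytest.raises(ValueError):
            apply_tempo(env, factor)


class TestGenerateNeural:
    def test_snr_must_be_positive(self, base_config):
        env = generate_envelope(base_config, "normal", np.random.default_rng(9))
        bad = dataclasses.replace(base_config, snr=0.0)
        with pytest.raises(ValueError, match="snr"):
            generate_neural(env, bad, np.random.default_rng(0))

    def test_finite_and_aligned(self, coupled_pair):
        env, neural = coupled_pair
        assert neural.trials.shape == env.trials.shape
        assert np.all(np.isfinite(neural.trials))

    def test_snr_scaling(self, base_config):
        """Configured SNR controls the oscillation-to-noise RMS ratio."""
        env = generate_envelope(base_config, "normal", np.random.default_rng(10))
        quiet = generate_neural(
            env,
            dataclasses.replace(base_config, snr=10.0),
            np.random.default_rng(1),
        )
        noisy = generate_neural(
            env,
            dataclasses.replace(base_config, snr=0.1),
            np.random.default_rng(1),
        )
        assert np.std(noisy.trials) > 3 * np.std(quiet.trials)


class TestGenerateCohort:
    def test_counts(self):
        cfg = SyntheticCohortConfig(
            n_subjects=3, n_trials=2, trial_duration=10.0, seed=0
        )
        cohort = generate_cohort(cfg)
        assert len(cohort.entries) == 3 * 3  # subjects x conditions
        n_traces = sum(len(e.neural) for e in cohort.entries)
        assert n_traces == 3 * 3 * 2  # x ROIs

    def test_bitwise_determinism(self):
        cfg = SyntheticCohortConfig(
            n_subjects=2, n_trials=2, trial_duration=10.0, seed=7
        )
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        for ea, eb in zip(a.entries, b.entries):
            np.testing.assert_array_equal(ea.envelope.trials, eb.envelope.trials)
            for roi in cfg.rois:
                np.testing.assert_array_equal(
                    ea.neural[roi].trials, eb.neural[roi].trials
                )
        assert a.ground_truth == b.ground_truth

    def test_zero_jitter_shares_ground_truth(self):
        cfg = SyntheticCohortConfig(
            n_subjects=3,
            n_trials=1,
            trial_duration=10.0,
            subject_rate_sd=0.0,
            subject_gamma_sd=0.0,
            seed=1,
        )
        cohort = generate_cohort(cfg)
        rates = {gt["syllable_rate"] for gt in cohort.ground_truth.values()}
        gammas = {gt["gamma_freq"] for gt in cohort.ground_truth.values()}
        assert rates == {cfg.syllable_rate}
        assert gammas == {cfg.gamma_freq}

    def test_same_base_envelope_across_conditions(self):
        """Tempo conditions re-render the same underlying stimulus."""
        cfg = SyntheticCohortConfig(n_subjects=1, n_trials=1,
                                    trial_duration=10.0, seed=3)
        cohort = generate_cohort(cfg)
        normal = cohort.get("S01", "normal").envelope
        acc = cohort.get("S01", "accelerated").envelope
        from speechpac.synthetic import apply_tempo as at

        np.testing.assert_allclose(at(normal, 1.25).trials, acc.trials)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 0},
            {"coupling_depth": 1.5},
            {"fs": 100.0},  # < 4 x gamma_freq
            {"tempo_factors": {"normal": 1.1}},
            {"tempo_factors": {"fast": 1.25}},
            {"snr": 1.0, "entrainment_strength": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(**kwargs)


def test_one_over_f_noise_slope():
    """Spectral slope of the shaped noise matches the exponent."""
    rng = np.random.default_rng(0)
    x = np.mean(
        [
            np.abs(np.fft.rfft(one_over_f_noise(8192, 1.0, rng))) ** 2
            for _ in range(50)
        ],
        axis=0,
    )
    f = np.fft.rfftfreq(8192)
    band = (f > 0.01) & (f < 0.4)
    slope = np.polyfit(np.log(f[band]), np.log(x[band]), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.15)
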