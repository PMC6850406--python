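"""MI estimation (plug-in + quadratic-extrapolation debiasing), binning,
comodulograms, surrogates and peak extraction."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from speechpac.pac import (
    Comodulogram,
    PacConfig,
    comodulogram,
    mi_bias_corrected,
    mi_plugin,
    pac_peak,
    quantize_equipopulated,
    surrogate_comodulogram,
)
from speechpac.synthetic import generate_neural


def mi_brute_force(phase_bins, amp_bins, n_bins):
    """Independent oracle: explicit double loop over the joint histogram."""
    n = len(phase_bins)
    mi = 0.0
    for i in range(n_bins):
        pi = np.sum(phase_bins == i) / n
        for j in range(n_bins):
            pj = np.sum(amp_bins == j) / n
            pij = np.sum((phase_bins == i) & (amp_bins == j)) / n
            if pij > 0:
                mi += pij * math.log2(pij / (pi * pj))
    return mi


class TestQuantize:
    def test_six_values_three_bins_equipopulated(self):
        bins = quantize_equipopulated([0.1, 0.4, 0.2, 0.9, 0.5, 0.7], 3)
        np.testing.assert_array_equal(np.bincount(bins), [2, 2, 2])
        # smallest two values in bin 0, largest two in bin 2
        assert bins[0] == 0 and bins[3] == 2

    def test_uniform_draws_exactly_balanced(self):
        rng = np.random.default_rng(0)
        bins = quantize_equipopulated(rng.uniform(size=1000), 10)
        np.testing.assert_array_equal(np.bincount(bins), np.full(10, 100))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            quantize_equipopulated(np.ones(100), 10)

    def test_ties_resolved_by_occurrence_order(self):
        bins = quantize_equipopulated([1.0, 1.0, 1.0, 2.0], 2)
        np.testing.assert_array_equal(bins, [0, 0, 1, 1])

    @given(seed=st.integers(0, 500), n=st.integers(50, 400))
    def test_counts_differ_by_at_most_one(self, seed, n):
        rng = np.random.default_rng(seed)
        bins = quantize_equipopulated(rng.standard_normal(n), 10)
        counts = np.bincount(bins, minlength=10)
        assert counts.max() - counts.min() <= 1


class TestMiPlugin:
    def test_fair_bit_bijection_is_one_bit(self):
        a = np.array([0, 1] * 500)
        assert mi_plugin(a, a, 2) == pytest.approx(1.0, abs=1e-12)

    def test_exact_independence_is_zero(self):
        # every (i, j) combination equally often: exactly independent
        i, j = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
        assert mi_plugin(i.ravel(), j.ravel(), 4) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_known_joint_distribution(self):
        """Joint ((0.4, 0.1), (0.1, 0.4)) has MI ~ 0.278 bits."""
        pb = np.repeat([0, 0, 1, 1], [8, 2, 2, 8])
        ab = np.repeat([0, 1, 0, 1], [8, 2, 2, 8])
        expected = 0.8 * math.log2(1.6) + 0.2 * math.log2(0.4)
        assert mi_plugin(pb, ab, 2) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.278, abs=5e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mi_plugin(np.zeros(10, int), np.zeros(11, int), 2)

    @given(seed=st.integers(0, 200))
    def test_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, 300)
        b = rng.integers(0, 10, 300)
        m = mi_plugin(a, b, 10)
        assert m == mi_plugin(b, a, 10)
        assert m >= 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.integers(0, 10, 400)
            b = (a + rng.integers(0, 3, 400)) % 10  # dependent pair
            assert mi_plugin(a, b, 10) == pytest.approx(
                mi_brute_force(a, b, 10), abs=1e-12
            )


class TestMiBiasCorrected:
    def test_deterministic_bijection_recovers_entropy(self):
        rng = np.random.default_rng(1)
        x = rng.permutation(np.repeat(np.arange(10), 1000))
        assert mi_bias_corrected(x, x, 10) == pytest.approx(
            math.log2(10), abs=0.02
        )

    def test_independent_series_debiased(self):
        """Corrected MI ~ 0 while plug-in carries the (B-1)^2/(2N ln2) bias."""
        rng = np.random.default_rng(2)
        n = 10_000
        corrected, plugin = [], []
        for _ in range(30):
            a = rng.integers(0, 10, n)
            b = rng.integers(0, 10, n)
            corrected.append(mi_bias_corrected(a, b, 10))
            plugin.append(mi_plugin(a, b, 10))
        first_order_bias = 81 / (2 * n * math.log(2))
        assert abs(np.mean(corrected)) < 0.01
        assert np.mean(plugin) == pytest.approx(first_order_bias, rel=0.5)

    def test_correction_reduces_estimate_on_independent_data(self):
        rng = np.random.default_rng(3)
        wins = 0
        for _ in range(40):
            a = rng.integers(0, 10, 1000)
            b = rng.integers(0, 10, 1000)
            if mi_bias_corrected(a, b, 10) <= mi_plugin(a, b, 10):
                wins += 1
        assert wins >= 38  # >= 95%

    def test_short_input_names_minimum(self):
        with pytest.raises(ValueError, match="400"):
            mi_bias_corrected(np.zeros(100, int), np.arange(100) % 10, 10)


@pytest.fixture(scope="module")
def reduced_cfg():
    """Comodulogram grids trimmed around the injected coupling for speed."""
    return PacConfig(
        phase_freqs=np.round(np.arange(3.0, 8.01, 0.5), 1),
        amp_freqs=np.round(np.arange(24.0, 42.01, 1.0), 1),
    )


class TestComodulogram:
    def test_recovers_injected_coupling(self, coupled_pair, reduced_cfg):
        env, neural = coupled_pair
        com = comodulogram(env, neural, "stimulus", reduced_cfg)
        peak = pac_peak(com)
        assert peak.f_phase == pytest.approx(5.5, abs=0.5)
        assert peak.f_amp == pytest.approx(33.0, abs=1.0)

    def test_phase_sources_agree_on_strong_coupling(
        self, coupled_pair, reduced_cfg
    ):
        env, neural = coupled_pair
        p_stim = pac_peak(comodulogram(env, neural, "stimulus", reduced_cfg))
        p_neur = pac_peak(comodulogram(env, neural, "neural", reduced_cfg))
        assert abs(p_stim.f_phase - p_neur.f_phase) <= 0.5
        assert abs(p_stim.f_amp - p_neur.f_amp) <= 1.0

    def test_no_coupling_no_structured_peak(
        self, base_config, coupled_pair, reduced_cfg
    ):
        """Without injected coupling the true cell does not stand out."""
        env, _ = coupled_pair
        cfg0 = dataclasses.replace(base_config, coupling_depth=0.0)
        neural0 = generate_neural(env, cfg0, np.random.default_rng(50))
        real = comodulogram(env, neural0, "stimulus", reduced_cfg)
        surr = surrogate_comodulogram(env, neural0, "stimulus", reduced_cfg)
        assert real.mi.max() < 2.0 * surr.mi.max()

    def test_unknown_phase_source_rejected(self, coupled_pair, reduced_cfg):
        env, neural = coupled_pair
        with pytest.raises(ValueError, match="phase_source"):
            comodulogram(env, neural, "audio", reduced_cfg)

    def test_bias_corrected_cells_bounded_below(self, coupled_pair,
                                                reduced_cfg):
        env, neural = coupled_pair
        com = comodulogram(env, neural, "stimulus", reduced_cfg)
        assert com.mi.min() > -0.05


class TestSurrogateComodulogram:
    def test_surrogate_below_real_when_coupled(self, coupled_pair,
                                               reduced_cfg):
        env, neural = coupled_pair
        real = comodulogram(env, neural, "stimulus", reduced_cfg)
        surr = surrogate_comodulogram(env, neural, "stimulus", reduced_cfg)
        assert surr.mi.max() < real.mi.max()

    def test_reversal_is_an_involution(self, coupled_pair, reduced_cfg):
        env, neural = coupled_pair
        real = comodulogram(env, neural, "stimulus", reduced_cfg)
        double = surrogate_comodulogram(
            env.reversed(), neural, "stimulus", reduced_cfg
        )
        np.testing.assert_allclose(double.mi, real.mi, atol=1e-12)


class TestPacPeak:
    def _comod(self, mi):
        mi = np.asarray(mi, dtype=float)
        return Comodulogram(
            phase_freqs=np.arange(1, mi.shape[0] + 1, dtype=float),
            amp_freqs=10 + np.arange(mi.shape[1], dtype=float),
            mi=mi,
        )

    def test_single_cell_mask_forces_choice(self):
        com = self._comod([[0.1, 0.9], [0.3, 0.2]])
        mask = np.zeros((2, 2), dtype=bool)
        mask[1, 0] = True
        peak = pac_peak(com, mask)
        assert (peak.mi_max, peak.f_phase, peak.f_amp) == (0.3, 2.0, 10.0)

    def test_full_mask_is_global_argmax(self):
        com = self._comod([[0.1, 0.9], [0.3, 0.2]])
        peak = pac_peak(com)
        assert (peak.mi_max, peak.f_phase, peak.f_amp) == (0.9, 1.0, 11.0)

    def test_tie_breaks_lowest_phase_then_amp(self):
        com = self._comod(np.full((3, 3), 0.5))
        peak = pac_peak(com)
        assert (peak.f_phase, peak.f_amp) == (1.0, 10.0)

    def test_empty_mask_rejected(self):
        com = self._comod([[0.1, 0.2]])
        with pytest.raises(ValueError, match="no significant cluster"):
            pac_peak(com, np.zeros((1, 2), dtype=bool))
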