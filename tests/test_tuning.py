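"""gDSI, preferred direction, modulation index, and the bootstrap test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import scmotion as sm
from scmotion.errors import InvalidParameterError, NoPreferenceError


def gdsi_oracle(curve, directions):
    """Brute-force vector sum, written independently of the implementation."""
    re = im = total = 0.0
    for r, d in zip(curve, directions):
        r = max(r, 0.0)
        re += r * np.cos(np.deg2rad(d))
        im += r * np.sin(np.deg2rad(d))
        total += r
    return np.sqrt(re**2 + im**2) / total


class TestGdsi:
    dirs = np.arange(0, 360, 45)

    def test_single_direction_response_is_one(self):
        assert sm.compute_gdsi([1, 0, 0, 0, 0, 0, 0, 0], self.dirs) == pytest.approx(1.0)

    def test_uniform_curve_is_zero(self):
        assert sm.compute_gdsi(np.ones(8), self.dirs) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_plus_peak_worked_example(self):
        # uniform part cancels in the vector sum; scalar sum is 9
        assert sm.compute_gdsi([2, 1, 1, 1, 1, 1, 1, 1], self.dirs) == pytest.approx(1 / 9)

    def test_negative_entries_rectified_before_computation(self):
        with_neg = sm.compute_gdsi([1.0, -0.5, 0.2, -1.0, 0.0, 0.1, 0.0, 0.0], self.dirs)
        rectified = sm.compute_gdsi([1.0, 0.0, 0.2, 0.0, 0.0, 0.1, 0.0, 0.0], self.dirs)
        assert with_neg == pytest.approx(rectified)

    def test_all_zero_curve_signals_undefined(self):
        assert np.isnan(sm.compute_gdsi(np.zeros(8), self.dirs))

    @given(st.lists(st.floats(-1.0, 5.0), min_size=8, max_size=8))
    def test_bounds_and_oracle_agreement(self, curve):
        if sum(max(c, 0.0) for c in curve) <= 0:
            return
        g = sm.compute_gdsi(curve, self.dirs)
        assert 0.0 <= g <= 1.0 + 1e-12
        assert g == pytest.approx(gdsi_oracle(curve, self.dirs), abs=1e-10)

    def test_unity_iff_single_nonzero_response(self):
        assert sm.compute_gdsi([0, 0, 3.2, 0, 0, 0, 0, 0], self.dirs) == pytest.approx(1.0)
        assert sm.compute_gdsi([0.1, 0, 3.2, 0, 0, 0, 0, 0], self.dirs) < 1.0


class TestPreferredDirection:
    @staticmethod
    def _matrix(center_alone=None, block=None):
        values = np.zeros((9, 9))
        if center_alone is not None:
            values[:8, 8] = center_alone
        if block is not None:
            values[:8, :8] = block
        return values

    def test_center_responsive_peak_of_center_alone_row(self):
        curve = np.zeros(8)
        curve[2] = 1.0  # 90 degrees
        d, source = sm.preferred_direction(self._matrix(center_alone=curve), True)
        assert (d, source) == (90.0, "center_alone")

    def test_center_silent_uses_center_direction_of_peak_cs_cell(self):
        block = np.zeros((8, 8))
        block[1, 5] = 2.0  # center 45, surround 225
        d, source = sm.preferred_direction(self._matrix(block=block), False)
        assert (d, source) == (45.0, "center_silent_CS")

    def test_tie_breaks_to_lowest_direction(self):
        curve = np.zeros(8)
        curve[0] = curve[4] = 1.0
        d, _ = sm.preferred_direction(self._matrix(center_alone=curve), True)
        assert d == 0.0

    def test_all_non_positive_signals_no_preference(self):
        with pytest.raises(NoPreferenceError):
            sm.preferred_direction(self._matrix(center_alone=-np.ones(8)), True)


class TestModulationIndex:
    def test_equal_responses_give_zero(self):
        assert sm.modulation_index(2.0, 2.0) == 0.0

    def test_worked_example(self):
        assert sm.modulation_index(3.0, 1.0) == pytest.approx(0.5)

    def test_negative_dff_clipped_to_minus_one(self):
        # raw value (-0.5 - 1) / (-0.5 + 1) = -3 -> clipped
        assert sm.modulation_index(-0.5, 1.0) == -1.0

    def test_denominator_zero_conventions(self):
        assert sm.modulation_index(0.0, 0.0) == 0.0
        assert sm.modulation_index(1.0, -1.0) == 1.0
        assert sm.modulation_index(-1.0, 1.0) == -1.0

    @given(a=st.floats(0.01, 10), b=st.floats(0.01, 10))
    def test_antisymmetric_under_argument_swap(self, a, b):
        assert sm.modulation_index(a, b) == pytest.approx(-sm.modulation_index(b, a), abs=1e-12)

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    def test_always_within_unit_interval(self, a, b):
        assert -1.0 <= sm.modulation_index(a, b) <= 1.0


class TestBootstrap:
    def test_identical_constant_trials_non_modulated(self):
        assert sm.bootstrap_classify([1, 1, 1, 1], [1, 1, 1, 1], seed=0) == "non_modulated"

    def test_clearly_separated_groups_potentiated(self):
        assert sm.bootstrap_classify([0, 0, 0, 0], [10, 10, 10, 10], seed=0) == "potentiated"

    def test_clearly_separated_groups_suppressed(self):
        assert sm.bootstrap_classify([10, 10, 10, 10], [0, 0, 0, 0], seed=0) == "suppressed"

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 4), rng.normal(0, 1, 4)
        assert sm.bootstrap_classify(a, b, seed=5) == sm.bootstrap_classify(a, b, seed=5)

    def test_mismatched_trial_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            sm.bootstrap_classify([1, 2, 3], [1, 2, 3, 4], seed=0)

    def test_too_few_resamples_rejected(self):
        with pytest.raises(InvalidParameterError):
            sm.bootstrap_classify([1, 2, 3, 4], [1, 2, 3, 4], n_boot=100, seed=0)

    def test_null_calibration_close_to_alpha(self):
        """Exchangeable-null type-I rate is near the nominal 5% (coarse unit
        check; the full-scale calibration lives in the acceptance suite)."""
        rng = np.random.default_rng(2)
        A = rng.normal(0, 1, (400, 4))
        B = rng.normal(0, 1, (400, 4))
        labels = sm.bootstrap_classify_batch(A, B, n_boot=2000, seed=3)
        rate = np.mean(labels != "non_modulated")
        assert abs(rate - 0.05) < 0.03


class TestCategorize:
    def test_unresponsive_cell_is_non_responsive(self):
        assert sm.categorize_cell(None, False) == "non_responsive"

    def test_surround_alone_only_responder_is_non_responsive(self):
        # responsive_to_center_or_cs excludes surround-alone conditions
        assert sm.categorize_cell("potentiated", False) == "non_responsive"

    def test_responsive_cell_carries_bootstrap_class(self):
        assert sm.categorize_cell("potentiated", True) == "potentiated"
        assert sm.categorize_cell("suppressed", True) == "suppressed"

    def test_strong_effect_excitatory_population_mostly_potentiated(self):
        """With the published opposite-surround law (a = 1.63) and low noise,
        at least 90% of excitatory cells classify as potentiated."""
        cfg = sm.excitatory_recovery_config()
        cfg.noise_sd = 0.02
        cells = sm.sample_population(cfg, 60, seed=81)
        protocol = sm.build_direction_contrast_protocol(8, 4, seed=0)
        trials = sm.simulate_trial_table(protocol, cells, seed=82)
        result = sm.analyze_trials(trials, protocol, n_boot=2000, seed=83)
        responsive = result.cells[result.cells.responsive_center]
        frac = (responsive["boot_opp"] == "potentiated").mean()
        assert frac >= 0.9
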