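"""dF/F0 extraction windows, trial tables, and the responsiveness criterion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import scmotion as sm
from scmotion.errors import (
    DegenerateBaselineError,
    InsufficientDataError,
    IntegrityError,
    InvalidParameterError,
    WindowError,
)
from scmotion.traces import WindowSpec, compute_dff


class TestDefaultWindows:
    def test_grating_fast_window_is_2p5_seconds(self):
        w = sm.default_windows("grating", "fast")
        assert w.baseline_pre_s == 1.25
        assert w.response_window(0.0, 2.0) == (0.25, 2.75)

    def test_grating_slow_window_shifted_375ms(self):
        w = sm.default_windows("grating", "slow_nuclear")
        assert w.response_window(0.0, 2.0) == (0.625, 3.125)

    def test_flash_fast_window_is_1p1_seconds(self):
        w = sm.default_windows("flash_square", "fast")
        assert w.baseline_pre_s == 0.75
        start, end = w.response_window(0.0, 1.0)
        assert (start, end) == (0.25, 1.35)
        assert end - start == pytest.approx(1.1)

    def test_unknown_combination_rejected(self):
        with pytest.raises(InvalidParameterError):
            sm.default_windows("flash_square", "slow_nuclear")
        with pytest.raises(InvalidParameterError):
            sm.default_windows("sparse_noise", "fast")

    def test_window_duration_arithmetic(self):
        for kind, ind, dur in [("grating", "fast", 2.0), ("grating", "slow_nuclear", 2.0), ("flash_square", "fast", 1.0)]:
            w = sm.default_windows(kind, ind)
            start, end = w.response_window(0.0, dur)
            assert end - start == pytest.approx(dur - w.response_start_offset_s + w.response_end_offset_s)


class TestComputeDff:
    window = WindowSpec(baseline_pre_s=2.0, response_start_offset_s=0.0, response_end_offset_s=0.0)

    def test_constant_trace_gives_zero(self):
        trace = np.full(8, 10.0)
        dff, f0, _ = compute_dff(trace, onset_s=2.0, offset_s=4.0, frame_rate_hz=1.0, window=self.window)
        assert dff == 0.0 and f0 == 10.0

    def test_doubling_response_gives_unity_dff(self):
        trace = np.array([10.0, 10.0, 20.0, 20.0, 10.0, 10.0])
        dff, _, _ = compute_dff(trace, 2.0, 4.0, 1.0, self.window)
        assert dff == pytest.approx(1.0)

    def test_worked_example(self):
        # baseline frames [10, 10], response frames [12, 13] -> (12.5-10)/10
        trace = np.array([10.0, 10.0, 12.0, 13.0, 10.0, 10.0])
        dff, f0, bsd = compute_dff(trace, 2.0, 4.0, 1.0, self.window)
        assert dff == pytest.approx(0.25)
        assert f0 == 10.0 and bsd == 0.0

    def test_negative_dff_retained(self):
        trace = np.array([10.0, 10.0, 8.0, 8.0, 10.0, 10.0])
        dff, _, _ = compute_dff(trace, 2.0, 4.0, 1.0, self.window)
        assert dff == pytest.approx(-0.2)

    @given(scale=st.floats(0.1, 100.0))
    def test_invariant_to_positive_trace_scaling(self, scale):
        trace = np.array([10.0, 11.0, 14.0, 13.0, 10.0, 10.0])
        base, _, _ = compute_dff(trace, 2.0, 4.0, 1.0, self.window)
        scaled, _, _ = compute_dff(trace * scale, 2.0, 4.0, 1.0, self.window)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(WindowError):
            compute_dff(np.full(4, 10.0), 2.0, 5.0, 1.0, self.window)
        with pytest.raises(WindowError):
            compute_dff(np.full(8, 10.0), 1.0, 3.0, 1.0, self.window)  # baseline before start

    def test_non_positive_baseline_rejected(self):
        trace = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        with pytest.raises(DegenerateBaselineError):
            compute_dff(trace, 2.0, 4.0, 1.0, self.window)


class TestResponsiveness:
    @staticmethod
    def _table(cond_means, sd_dff=0.1, n_rep=4, f0=100.0):
        rows = []
        for cond, mean in enumerate(cond_means):
            for rep in range(n_rep):
                rows.append((0, cond, rep, mean, f0, sd_dff * f0))
        return pd.DataFrame(rows, columns=["cell_id", "condition", "repeat", "dff", "F0", "baseline_sd"])

    def test_zero_mean_with_positive_sd_is_non_responsive(self):
        responsive, flags = sm.assess_responsiveness(self._table([0.0] * 5))
        assert not responsive and not flags.any()

    def test_one_strong_condition_is_responsive(self):
        responsive, flags = sm.assess_responsiveness(self._table([0.0, 0.0, 1.0]))
        assert responsive and flags.sum() == 1

    def test_threshold_is_twice_pooled_baseline_sd(self):
        # sd in dff units is 0.1 -> threshold 0.2
        responsive, _ = sm.assess_responsiveness(self._table([0.19]))
        assert not responsive
        responsive, _ = sm.assess_responsiveness(self._table([0.21]))
        assert responsive

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            sm.assess_responsiveness(self._table([])[0:0])

    def test_null_population_false_positive_rate_matches_monte_carlo_oracle(self):
        """On noise-only cells the criterion's empirical responsive fraction
        agrees with an independent Monte-Carlo simulation of window means."""
        protocol = sm.build_direction_contrast_protocol(2, 4, seed=0)
        cfg = sm.GeneratorConfig(excitatory_fraction=1.0)
        cfg.excitatory.response_fractions = (0.0, 0.0, 1.0)
        cells = sm.sample_population(cfg, 1000, seed=71)
        rec = sm.simulate_recording(protocol, cells, seed=72)
        trials = sm.build_response_table(rec)
        flags = sm.responsiveness_table(trials)
        pipeline_rate = flags.groupby("cell_id")["responsive"].first().mean()

        # independent oracle: gaussian window means with the matched frame counts
        rng = np.random.default_rng(73)
        n_base = int(round(1.25 * 8.079))
        n_resp = int(round(2.5 * 8.079))
        n_cells_mc, n_cond, n_rep = 4000, protocol.n_conditions, 4
        sd = cfg.noise_sd
        base_noise = rng.normal(0, sd / np.sqrt(n_base), (n_cells_mc, n_cond, n_rep))
        resp_noise = rng.normal(0, sd / np.sqrt(n_resp), (n_cells_mc, n_cond, n_rep))
        dff = resp_noise - base_noise
        cond_means = dff.mean(axis=2)
        oracle_rate = (cond_means > 2 * sd).any(axis=1).mean()
        assert abs(pipeline_rate - oracle_rate) <= 0.01


class TestResponseTable:
    def test_row_count_cells_by_conditions_by_repeats(self):
        protocol = sm.build_direction_contrast_protocol(8, 4, seed=0)
        cells = sm.sample_population(sm.GeneratorConfig(), 10, seed=1)
        rec = sm.simulate_recording(protocol, cells, seed=2)
        table = sm.build_response_table(rec)
        assert len(table) == 81 * 4 * 10

    def test_deterministic_on_same_input(self):
        protocol = sm.build_direction_contrast_protocol(2, 2, seed=0)
        cells = sm.sample_population(sm.GeneratorConfig(), 2, seed=1)
        rec = sm.simulate_recording(protocol, cells, seed=2)
        assert sm.build_response_table(rec).equals(sm.build_response_table(rec))

    def test_event_protocol_mismatch_rejected(self):
        protocol = sm.build_direction_contrast_protocol(2, 2, seed=0)
        cells = sm.sample_population(sm.GeneratorConfig(), 2, seed=1)
        rec = sm.simulate_recording(protocol, cells, seed=2)
        rec.events = rec.events.iloc[:-1]  # drop one presentation
        with pytest.raises(IntegrityError):
            sm.build_response_table(rec)
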