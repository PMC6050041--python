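"""Response matrices, alignment, population curves, and modulation fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import scmotion as sm
from scmotion.errors import DegenerateFitError, IncompleteMatrixError
from scmotion.surround import ResponseMatrix


def ols_oracle(x, y):
    """Normal-equations least squares, independent of the fitting routine."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return beta[1], beta[0], r2


def make_matrix(values, cell_id=0):
    values = np.asarray(values, dtype=float)
    return ResponseMatrix(cell_id, values, values[..., None], tuple(np.arange(0, 360, 45.0)))


class TestBuildMatrix:
    def test_entries_are_repeat_means(self, noiseless_run):
        trials = noiseless_run["trials"]
        sub = trials[trials.cell_id == 0]
        m = sm.build_matrix(sub, noiseless_run["protocol"])
        by_cond = sub.groupby("condition")["dff"].mean()
        assert m.values[0, 0] == pytest.approx(by_cond.loc[0])
        assert m.trials.shape == (9, 9, 4)

    def test_noiseless_matrix_equals_generative_law(self, noiseless_run):
        trials = noiseless_run["trials"]
        cell = noiseless_run["cells"][1]
        m = sm.build_matrix(trials[trials.cell_id == 1], noiseless_run["protocol"])
        expected = sm.expected_response_matrix(cell, noiseless_run["protocol"])
        assert np.abs(m.values - expected).max() < 0.01

    def test_all_gray_condition_near_zero_for_noiseless_data(self, noiseless_run):
        trials = noiseless_run["trials"]
        m = sm.build_matrix(trials[trials.cell_id == 0], noiseless_run["protocol"])
        assert abs(m.values[8, 8]) < 0.01

    def test_missing_condition_rejected(self, noiseless_run):
        trials = noiseless_run["trials"]
        sub = trials[(trials.cell_id == 0) & (trials.condition != 40)]
        with pytest.raises(IncompleteMatrixError):
            sm.build_matrix(sub, noiseless_run["protocol"])


class TestAlignment:
    def test_preferred_zero_is_identity(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.random((9, 9)))
        aligned = sm.align_matrix(m, 0.0)
        assert np.array_equal(aligned.values, m.values)

    def test_preferred_90_moves_entry_to_relative_frame(self):
        values = np.zeros((9, 9))
        values[2, 6] = 7.0  # center 90, surround 270
        aligned = sm.align_matrix(make_matrix(values), 90.0)
        assert aligned.values[0, 4] == 7.0  # relative (0, 180)

    def test_blank_row_and_column_fixed(self):
        values = np.zeros((9, 9))
        values[8, 8] = 3.0
        values[2, 8] = 5.0  # center 90 alone
        aligned = sm.align_matrix(make_matrix(values), 90.0)
        assert aligned.values[8, 8] == 3.0
        assert aligned.values[0, 8] == 5.0

    def test_alignment_idempotent(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.random((9, 9)))
        once = sm.align_matrix(m, 135.0)
        twice = sm.align_matrix(once, 135.0)
        assert np.array_equal(once.values, twice.values)

    @given(pref=st.sampled_from([0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0]))
    def test_alignment_conserves_entry_multiset(self, pref):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.random((9, 9)))
        aligned = sm.align_matrix(m, pref)
        assert np.allclose(np.sort(aligned.values.ravel()), np.sort(m.values.ravel()))
        assert aligned.values.sum() == pytest.approx(m.values.sum())


class TestPopulationCurves:
    def test_identical_cells_have_zero_sem(self):
        values = np.arange(81, dtype=float).reshape(9, 9)
        curves = sm.population_curves([make_matrix(values, i) for i in range(3)])
        for df in curves.values():
            assert np.allclose(df["sem"], 0.0)

    def test_opposite_surround_curve_above_center_alone(self, recovery_run):
        mats = recovery_run["result"].matrices_for(recovery_run["result"].cells["responsive_center"])
        curves = sm.population_curves(mats)
        assert (curves["opposite"]["mean"] >= curves["center_alone"]["mean"]).all()

    def test_same_surround_curve_below_center_alone(self, recovery_run):
        mats = recovery_run["result"].matrices_for(recovery_run["result"].cells["responsive_center"])
        curves = sm.population_curves(mats)
        assert (curves["same"]["mean"] <= curves["center_alone"]["mean"]).all()


class TestFitModulation:
    def test_pure_multiplication_recovered_exactly(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
        fit = sm.fit_modulation(x, 2 * x)
        assert fit.slope == pytest.approx(2.0) and fit.intercept == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_affine_relation_recovered_exactly(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
        fit = sm.fit_modulation(x, 0.5 * x + 1.0)
        assert fit.slope == pytest.approx(0.5) and fit.intercept == pytest.approx(1.0)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(DegenerateFitError):
            sm.fit_modulation(np.ones(8), np.arange(8.0))

    def test_confidence_interval_brackets_slope(self):
        rng = np.random.default_rng(3)
        x = np.arange(8.0)
        y = 1.5 * x + rng.normal(0, 0.2, 8)
        fit = sm.fit_modulation(x, y)
        lo, hi = fit.slope_ci_95
        assert lo < fit.slope < hi

    @given(seed=st.integers(0, 1000))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 8)
        if np.ptp(x) == 0:
            return
        y = rng.normal(0, 1, 8)
        fit = sm.fit_modulation(x, y)
        slope, intercept, r2 = ols_oracle(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)


class TestSlopesVsDeltaTheta:
    def test_recovery_population_slopes_increase_with_direction_difference(self, recovery_run):
        mats = recovery_run["result"].matrices_for(recovery_run["result"].cells["responsive_center"])
        fits = sm.slopes_vs_delta_theta(mats)
        slopes = [fits[d].slope for d in (0, 45, 90, 135, 180)]
        assert all(b > a for a, b in zip(slopes, slopes[1:]))

    def test_no_modulation_control_gives_unit_slopes(self, protocol81):
        cfg = sm.excitatory_recovery_config()
        for d in (0, 45, 90, 135, 180):
            cfg.excitatory.slopes[d] = 1.0
            cfg.excitatory.intercepts_pct[d] = 0.0
        cfg.excitatory.slope_jitter_sd = 0.0
        cfg.excitatory.intercept_jitter_pct_sd = 0.0
        cfg.excitatory.a180_kappa_coupling = 0.0
        cfg.noise_sd = 0.02
        cells = sm.sample_population(cfg, 60, seed=91)
        trials = sm.simulate_trial_table(protocol81, cells, seed=92)
        result = sm.analyze_trials(trials, protocol81, n_boot=2000, seed=93)
        mats = result.matrices_for(result.cells["responsive_center"])
        fits = sm.slopes_vs_delta_theta(mats)
        for fit in fits.values():
            assert fit.slope == pytest.approx(1.0, abs=0.05)

    def test_normalized_fits_reach_same_conclusions(self, recovery_run):
        mats = recovery_run["result"].matrices_for(recovery_run["result"].cells["responsive_center"])
        fits = sm.slopes_vs_delta_theta(mats, normalize=True)
        slopes = [fits[d].slope for d in (0, 45, 90, 135, 180)]
        assert all(b > a for a, b in zip(slopes, slopes[1:]))
        assert fits[0].slope < 1 < fits[180].slope

    def test_inhibitory_population_opposite_slope_below_same_slope(self, mixed_run):
        result = mixed_run["result"]
        mask = (result.cells["cell_class"] == "inhibitory") & result.cells["responsive_center"]
        fits = sm.slopes_vs_delta_theta(result.matrices_for(mask))
        assert fits[180].slope < fits[0].slope


class TestPerCellFits:
    def test_noiseless_multiplicative_cell_fits_perfectly(self):
        x = np.array([5, 8, 3, 1, 0.5, 1, 3, 4.0])
        values = np.zeros((9, 9))
        values[:8, 8] = x
        for k in range(8):
            idx = np.arange(8)
            values[idx, (idx + k) % 8] = 1.3 * x
        fits = sm.per_cell_fits([make_matrix(values)])
        assert (fits["r_squared"] > 0.999).all()
        assert np.allclose(fits["intercept"], 0.0, atol=1e-9)

    def test_pure_noise_cell_filtered_out(self, protocol81):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 0.01, (9, 9))
        fits = sm.per_cell_fits([make_matrix(values)])
        assert not fits["passes_filter"].all()

    def test_mean_filtered_slope_increases_with_direction_difference(self, recovery_run):
        mats = recovery_run["result"].matrices_for(recovery_run["result"].cells["responsive_center"])
        means = sm.mean_filtered_slopes(sm.per_cell_fits(mats))
        assert means.loc[180] > means.loc[90] > means.loc[0]


class TestCenterSilentCurve:
    def test_noiseless_center_silent_curve_equals_intercept_law(self, protocol81):
        cfg = sm.GeneratorConfig(excitatory_fraction=1.0)
        cfg.noise_sd = 0.0
        cfg.excitatory.response_fractions = (0.0, 1.0, 0.0)
        cells = sm.sample_population(cfg, 5, seed=95)
        trials = sm.simulate_trial_table(protocol81, cells, seed=96)
        mats = [sm.build_matrix(trials[trials.cell_id == i], protocol81) for i in range(5)]
        curve, center_ref = sm.center_silent_curve(mats)
        expected = np.mean([[c.modulation_law[d][1] for d in (0, 45, 90, 135, 180)] for c in cells], axis=0)
        assert np.allclose(curve["mean"], expected, atol=1e-9)
        assert center_ref == pytest.approx(0.0, abs=1e-9)

    def test_curve_monotone_on_default_population(self, mixed_run):
        result = mixed_run["result"]
        cells = mixed_run["cells"]
        ids = [i for i, c in enumerate(cells) if c.center_silent and i in result.matrices]
        mats = [result.matrices[i] for i in ids]
        curve, _ = sm.center_silent_curve(mats)
        vals = curve["mean"].to_numpy()
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestSummation:
    def test_inhibitory_opposite_surround_sublinear(self, protocol81):
        cfg = sm.GeneratorConfig(excitatory_fraction=0.0)
        cfg.noise_sd = 0.0
        cfg.inhibitory.response_fractions = (1.0, 0.0, 0.0)
        cfg.inhibitory.surround_alone_prob = 1.0
        cells = sm.sample_population(cfg, 4, seed=97)
        trials = sm.simulate_trial_table(protocol81, cells, seed=98)
        mats = [sm.build_matrix(trials[trials.cell_id == i], protocol81) for i in range(4)]
        comp = sm.summation_comparison(mats)
        opp = comp[comp.delta_theta == 180]
        assert (opp["mean_difference"] < 0).all()

    def test_no_surround_response_reduces_to_modulation_difference(self):
        values = np.zeros((9, 9))
        x = np.linspace(1, 2, 8)
        values[:8, 8] = x
        idx = np.arange(8)
        values[idx, idx] = 0.5 * x  # same-direction suppression, no surround-alone rows
        comp = sm.summation_comparison([make_matrix(values)])
        same = comp[comp.delta_theta == 0]["mean_difference"].iloc[0]
        assert same == pytest.approx(np.mean(0.5 * x - x))

    def test_additive_control_gives_zero_difference(self):
        rng = np.random.default_rng(5)
        center = rng.random(8)
        surround = rng.random(8)
        values = np.zeros((9, 9))
        values[:8, 8] = center
        values[8, :8] = surround
        values[:8, :8] = center[:, None] + surround[None, :]
        comp = sm.summation_comparison([make_matrix(values)])
        assert np.allclose(comp["mean_difference"], 0.0, atol=1e-12)


@pytest.fixture(scope="module")
def feature_mis(protocol81):
    cells = sm.sample_population(sm.GeneratorConfig(), 300, seed=61)
    trials = sm.simulate_trial_table(protocol81, cells, seed=62)
    result = sm.analyze_trials(trials, protocol81, n_boot=2000, seed=63)
    d = result.cells.set_index("cell_id")
    d["cell_class"] = [c.cell_class for c in cells]
    pref = d.loc[d.responsive_center, "preferred_direction"]
    ref = d.loc[d.responsive_center, "r_pref_c"]
    out = {}
    for kind in ("anti_phase", "temporal_freq", "static_orientation"):
        proto = sm.build_feature_contrast_protocol(kind, 4, seed=7)
        ftrials = sm.simulate_trial_table(proto, cells, seed=64)
        mi = sm.feature_contrast_mi(ftrials, proto, pref_dirs=pref, r_pref_c=ref)
        out[kind] = mi.merge(d[["cell_class"]], left_on="cell_id", right_index=True)
    out["direction"] = d
    return out


class TestFeatureContrast:
    def test_excitatory_anti_phase_between_same_and_opposite(self, feature_mis):
        d = feature_mis["direction"]
        exc = d[(d.cell_class == "excitatory") & d.responsive_center]
        anti = feature_mis["anti_phase"]
        anti_med = anti[anti.cell_class == "excitatory"]["mi"].median()
        assert exc["mi_same"].median() < anti_med < exc["mi_opp"].median()

    def test_inhibitory_opposite_more_suppressive_than_anti_phase(self, feature_mis):
        d = feature_mis["direction"]
        inh = d[(d.cell_class == "inhibitory") & d.responsive_center]
        anti = feature_mis["anti_phase"]
        anti_med = anti[anti.cell_class == "inhibitory"]["mi"].median()
        assert inh["mi_opp"].median() < anti_med

    def test_static_cross_less_suppressive_than_iso_for_both_classes(self, feature_mis):
        static = feature_mis["static_orientation"]
        for cls in ("excitatory", "inhibitory"):
            sub = static[static.cell_class == cls]
            iso = sub[sub.tag == "static_iso"]["mi"].median()
            cross = sub[sub.tag == "static_cross"]["mi"].median()
            assert cross > iso
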