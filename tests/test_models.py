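"""Model fits, contrasts, BH adjustment and the end-to-end workflow."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from dianova.errors import DataError
from dianova.models import (P_FLOOR, adjust_bh, fit_combined, fit_combined_all,
                            fit_single_level, omnibus_test, run_workflow,
                            test_contrast)
from dianova.preprocess import (ProteinRunMatrix, center_precursors,
                                summarize_protein)

from conftest import complete_quant, make_design


def single_level_matrix(design, values, ms_level=1, protein="P1"):
    return ProteinRunMatrix(pd.DataFrame({
        "protein_id": protein, "run_id": design.runs,
        "ms_level": ms_level, "value": np.asarray(values, float),
    }), centered=False)


def combined_matrix(design, y1, y2, protein="P1"):
    frames = [pd.DataFrame({"protein_id": protein, "run_id": design.runs,
                            "ms_level": lvl, "value": np.asarray(y, float)})
              for lvl, y in ((1, y1), (2, y2))]
    return ProteinRunMatrix(pd.concat(frames, ignore_index=True), centered=True)


class TestSingleLevelFit:
    def test_zero_noise_separation(self):
        """Groups {0,0} vs {1,1}: deviations ±0.5, MS_Error 0, p at the floor."""
        design = make_design({"A": 2, "B": 2})
        fit = fit_single_level(single_level_matrix(design, [0, 0, 1, 1]), design, 1)
        np.testing.assert_allclose(fit.group_effects, [-0.5, 0.5])
        assert fit.ms_error == 0
        assert fit.perfect_separation
        assert np.isinf(fit.f_stat)
        assert fit.p_value == P_FLOOR

    def test_constant_values_untestable(self):
        design = make_design({"A": 2, "B": 2})
        fit = fit_single_level(single_level_matrix(design, [3, 3, 3, 3]), design, 1)
        assert fit.untestable and "constant" in fit.reason

    def test_matches_ols_group_indicator_regression(self, design_3x4):
        """F and p agree with a generic least-squares oracle to 1e-8."""
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 12) + np.repeat([0.0, 0.4, 1.1], 4)
        fit = fit_single_level(single_level_matrix(design_3x4, y), design_3x4, 1)
        frame = pd.DataFrame({"y": y, "g": np.repeat(design_3x4.groups, 4)})
        oracle = anova_lm(smf.ols("y ~ C(g)", frame).fit())
        assert abs(fit.f_stat - oracle["F"].iloc[0]) < 1e-8
        assert abs(fit.p_value - oracle["PR(>F)"].iloc[0]) < 1e-8
        assert abs(fit.ms_error - oracle["mean_sq"].iloc[1]) < 1e-10

    def test_group_effects_sum_to_zero(self, design_3x4):
        rng = np.random.default_rng(6)
        fit = fit_single_level(
            single_level_matrix(design_3x4, rng.normal(0, 1, 12)), design_3x4, 1)
        assert abs(fit.group_effects.sum()) < 1e-10


class TestCombinedFit:
    def test_duplicated_levels_collapse_to_run_mean_anova(self, design_3x4):
        """If MS2 == MS1 exactly, MS_i = 0, MS_Error = 0, sigma_R² = MS_Rep/2
        and the Group F equals a one-way ANOVA on the run means."""
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1, 12) + np.repeat([0.0, 0.5, 1.0], 4)
        fit = fit_combined(combined_matrix(design_3x4, y, y), design_3x4)
        np.testing.assert_allclose(fit.ms_effects, [0.0, 0.0], atol=1e-12)
        assert fit.ms_error < 1e-20
        np.testing.assert_allclose(fit.sigma_r2, fit.ms_rep / 2, atol=1e-12)
        ref = fit_single_level(single_level_matrix(design_3x4, y), design_3x4, 1)
        np.testing.assert_allclose(fit.f_stat, ref.f_stat, rtol=1e-10)

    def test_sigma_r2_truncated_to_zero_when_ms_rep_below_ms_error(self):
        design = make_design({"A": 2, "B": 2})
        # run means nearly equal within groups, large level-level residuals
        y1 = [0.00, 1.00, 0.50, 1.52]
        y2 = [1.02, 0.00, 1.50, 0.50]
        fit = fit_combined(combined_matrix(design, y1, y2), design)
        assert fit.ms_rep < fit.ms_error
        assert fit.truncated and fit.sigma_r2 == 0.0
        assert not fit.untestable

    def test_balanced_closed_form_agrees_with_reml_oracle(self, design_3x4):
        """Group contrast p matches a REML mixed-model fit to 1e-6."""
        from statsmodels.regression.mixed_linear_model import MixedLM
        rng = np.random.default_rng(12)
        rep = rng.normal(0, 0.3, 12)
        base = np.repeat([0.0, 0.5, 1.0], 4) + rep
        y1 = base + rng.normal(0, 0.2, 12)
        y2 = base + rng.normal(0, 0.2, 12)
        fit = fit_combined(combined_matrix(design_3x4, y1, y2), design_3x4)
        assert not fit.truncated
        row = test_contrast(fit, "g2", "g1")

        endog = np.concatenate([y1, y2])
        codes = np.tile(np.repeat([0, 1, 2], 4), 2)
        eff = np.zeros((24, 2))
        eff[codes == 0, 0] = 1
        eff[codes == 1, 1] = 1
        eff[codes == 2, :] = -1
        exog = np.column_stack([np.ones(24),
                                np.concatenate([np.ones(12), -np.ones(12)]), eff])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # oracle optimizer chatter
            res = MixedLM(endog, exog, groups=np.tile(np.arange(12), 2)).fit(
                reml=True, method="powell", xtol=1e-12, ftol=1e-12)
        est = res.fe_params[3] - res.fe_params[2]      # g2 - g1 effect
        c = np.array([0.0, 0.0, -1.0, 1.0])
        var = c @ np.asarray(res.cov_params())[:4, :4] @ c
        t = est / np.sqrt(var)
        p = 2 * stats.t.sf(abs(t), 3 * (4 - 1))
        assert abs(row["log2fc"] - est) < 1e-6
        assert abs(row["p_value"] - p) < 1e-6
        assert abs(fit.sigma_r2 - float(np.asarray(res.cov_re)[0, 0])) < 1e-5
        assert abs(fit.sigma2 - res.scale) < 1e-5

    def test_reml_fallback_on_unbalanced_design_matches_balanced_limit(self, design_3x4):
        """REML path on a balanced design reproduces the closed form."""
        rng = np.random.default_rng(13)
        rep = rng.normal(0, 0.3, 12)
        base = np.repeat([0.0, 0.5, 1.0], 4) + rep
        y1 = base + rng.normal(0, 0.2, 12)
        y2 = base + rng.normal(0, 0.2, 12)
        from dianova.models import _fit_combined_reml
        closed = fit_combined(combined_matrix(design_3x4, y1, y2), design_3x4)
        reml = _fit_combined_reml("P1", np.asarray(y1), np.asarray(y2), design_3x4)
        assert reml.reml
        np.testing.assert_allclose(reml.group_means, closed.group_means, atol=1e-6)
        assert abs(reml.sigma_r2 - closed.sigma_r2) < 1e-4
        assert abs(reml.p_value - closed.p_value) < 1e-5

    def test_unbalanced_design_is_handled(self):
        design = make_design({"A": 4, "B": 3})
        rng = np.random.default_rng(14)
        n = len(design.runs)
        base = np.where(np.array([g == "B" for g in design.data["group"]]), 1.0, 0.0) \
            + rng.normal(0, 0.3, n)
        fit = fit_combined(combined_matrix(design, base + rng.normal(0, 0.2, n),
                                           base + rng.normal(0, 0.2, n)), design)
        assert fit.reml
        assert fit.df_rep == n - 2          # containment df = sum_g (R_g - 1)
        assert 0 <= fit.p_value <= 1
        row = test_contrast(fit, "B", "A")
        assert 0 < row["p_value"] < 1 and row["log2fc"] == pytest.approx(1.0, abs=0.8)


class TestContrasts:
    def test_identical_group_means_give_t_zero_p_one(self, design_2x3):
        fit = fit_single_level(
            single_level_matrix(design_2x3, [1, 2, 3, 1, 2, 3]), design_2x3, 1)
        row = test_contrast(fit, "B", "A")
        assert row["log2fc"] == 0.0
        assert row["statistic"] == 0.0
        assert row["p_value"] == 1.0

    def test_two_group_t_squared_equals_omnibus_f(self, design_2x3):
        rng = np.random.default_rng(21)
        fit = fit_single_level(
            single_level_matrix(design_2x3, rng.normal(0, 1, 6)), design_2x3, 1)
        row = test_contrast(fit, "B", "A")
        assert row["statistic"] ** 2 == pytest.approx(fit.f_stat, rel=1e-10)
        assert row["p_value"] == pytest.approx(fit.p_value, rel=1e-10)

    def test_unknown_group_label_rejected(self, design_2x3):
        fit = fit_single_level(
            single_level_matrix(design_2x3, [1, 2, 3, 4, 5, 6]), design_2x3, 1)
        with pytest.raises(DataError, match="nope"):
            test_contrast(fit, "nope", "A")

    def test_scale_equivariance(self, design_3x4):
        """Adding a constant shifts mu only; statistics unchanged to 1e-10."""
        rng = np.random.default_rng(22)
        y = rng.normal(0, 1, 12)
        f0 = fit_single_level(single_level_matrix(design_3x4, y), design_3x4, 1)
        f1 = fit_single_level(single_level_matrix(design_3x4, y + 7.5), design_3x4, 1)
        assert f1.mu == pytest.approx(f0.mu + 7.5, abs=1e-10)
        assert f1.f_stat == pytest.approx(f0.f_stat, abs=1e-10)
        r0, r1 = test_contrast(f0, "g2", "g1"), test_contrast(f1, "g2", "g1")
        assert r1["statistic"] == pytest.approx(r0["statistic"], abs=1e-10)


class TestBenjaminiHochberg:
    def test_hand_derived_step_up_values(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_singleton(self):
        np.testing.assert_allclose(adjust_bh([1.0]), [1.0])

    def test_adjusted_at_least_raw_and_rank_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 50)
        q = adjust_bh(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            adjust_bh([0.5, 1.2])


@pytest.fixture(scope="module")
def small_quant(design_2x3):
    rng = np.random.default_rng(30)
    values = {}
    for k in range(6):
        shift = 1.5 if k < 2 else 0.0
        base = 12 + rng.normal(0, 0.5)
        values[(f"P{k}", f"P{k}_q1")] = {
            r: tuple(base + (shift if r.startswith("B") else 0)
                     + rng.normal(0, 0.2, 2))
            for r in design_2x3.runs}
        values[(f"P{k}", f"P{k}_q2")] = {
            r: tuple(base + 0.5 + (shift if r.startswith("B") else 0)
                     + rng.normal(0, 0.2, 2))
            for r in design_2x3.runs}
    return complete_quant(values, scale="log2")


class TestRunWorkflow:
    def test_each_protein_appears_once_per_contrast(self, small_quant, design_2x3):
        table = run_workflow(small_quant, design_2x3, "combined", contrasts="both")
        counts = table.data.groupby(["protein_id", "contrast"]).size()
        assert (counts == 1).all()
        assert set(table.data["contrast"]) == {"omnibus", "A_vs_B"}

    def test_orchestration_equals_manual_chain(self, small_quant, design_2x3):
        table = run_workflow(small_quant, design_2x3, "ms1", contrasts="omnibus")
        mat = summarize_protein(small_quant, design_2x3)
        rows = []
        for pid in mat.proteins:
            fit = fit_single_level(
                ProteinRunMatrix(mat.for_protein(pid), centered=False), design_2x3, 1)
            rows.append(omnibus_test(fit))
        manual = pd.DataFrame(rows)
        manual["adj_p_value"] = adjust_bh(manual["p_value"].to_numpy())
        merged = table.data.merge(manual, on="protein_id", suffixes=("", "_m"))
        np.testing.assert_allclose(merged["p_value"], merged["p_value_m"], atol=1e-12)
        np.testing.assert_allclose(merged["adj_p_value"], merged["adj_p_value_m"],
                                   atol=1e-12)

    def test_single_group_design_yields_untestable_report(self, small_quant):
        design = make_design({"A": 3})
        quant = small_quant.with_data(
            small_quant.data[small_quant.data["run_id"].isin(design.runs)])
        table = run_workflow(quant, design, "ms1")
        assert table.n_results == 0
        assert len(table.untestable) == 6
        assert (table.untestable["reason"] == "single-group design").all()

    def test_combined_centers_internally(self, small_quant, design_2x3):
        auto = run_workflow(small_quant, design_2x3, "combined", contrasts="omnibus")
        manual = run_workflow(center_precursors(small_quant), design_2x3,
                              "combined", contrasts="omnibus")
        np.testing.assert_allclose(auto.data["p_value"], manual.data["p_value"],
                                   atol=1e-12)

    def test_centered_input_rejected_for_single_level(self, small_quant, design_2x3):
        with pytest.raises(DataError, match="uncentered"):
            run_workflow(center_precursors(small_quant), design_2x3, "ms1")

    def test_explicit_contrast_list(self, small_quant, design_2x3):
        table = run_workflow(small_quant, design_2x3, "ms2", contrasts=[("B", "A")])
        assert set(table.data["contrast"]) == {"B_vs_A"}
        assert (table.data["method"] == "ms2").all()


def test_fit_combined_all_matches_per_protein(design_2x3):
    rng = np.random.default_rng(44)
    frames = []
    for pid in ("P1", "P2", "P3"):
        for lvl in (1, 2):
            frames.append(pd.DataFrame({
                "protein_id": pid, "run_id": design_2x3.runs, "ms_level": lvl,
                "value": rng.normal(0, 1, 6)}))
    mat = ProteinRunMatrix(pd.concat(frames, ignore_index=True), centered=True)
    fits = fit_combined_all(mat, design_2x3)
    assert [f.protein_id for f in fits] == ["P1", "P2", "P3"]
    solo = fit_combined(ProteinRunMatrix(mat.for_protein("P2"), centered=True),
                        design_2x3)
    np.testing.assert_allclose(fits[1].f_stat, solo.f_stat, atol=1e-12)
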