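"""Composite Z, gamma GLM, mixed model, and adjusted increments."""

import numpy as np
import pandas as pd
import pytest

from mapt_cea import (TariffTable, TrialConfig, adjusted_increments,
                      composite_z, fit_cost_glm, fit_z_mixed, generate_trial,
                      predictor_matrix)
from mapt_cea.synthetic_trial import ARMS, COGNITIVE_TESTS


def panel_from_scores(scores):
    """Cognition frame from {pid: {month: value}} using the same value for
    all four tests (so the composite equals the standardised value)."""
    rows = []
    for pid, by_month in scores.items():
        for month, val in by_month.items():
            rows.append({"participant_id": pid, "month": month,
                         **{t: val for t in COGNITIVE_TESTS}})
    return pd.DataFrame(rows)


class TestCompositeZ:
    def test_participant_at_cohort_mean_scores_zero(self):
        panel = panel_from_scores({1: {0: 10.0, 36: 10.0},
                                   2: {0: 20.0, 36: 20.0},
                                   3: {0: 30.0, 36: 30.0}})
        comp = composite_z(panel)
        z = comp.panel.set_index(["participant_id", "month"])["z"]
        assert z[(2, 0)] == pytest.approx(0.0)

    def test_one_sd_above_mean_scores_one(self):
        panel = panel_from_scores({i: {0: v, 36: v}
                                   for i, v in enumerate([8, 9, 10, 11, 12])})
        comp = composite_z(panel)
        sd = np.std([8, 9, 10, 11, 12], ddof=1)
        z = comp.panel.set_index(["participant_id", "month"])["z"]
        assert z[(4, 0)] == pytest.approx((12 - 10) / sd)

    def test_missing_component_makes_composite_missing(self):
        panel = panel_from_scores({1: {0: 10.0, 36: 11.0},
                                   2: {0: 20.0, 36: 19.0}})
        panel.loc[(panel["participant_id"] == 1) & (panel["month"] == 36),
                  "dsst"] = np.nan
        comp = composite_z(panel)
        z = comp.panel.set_index(["participant_id", "month"])["z"]
        assert np.isnan(z[(1, 36)])
        assert not np.isnan(z[(2, 36)])
        assert np.isnan(comp.change_36m[1])

    def test_zero_baseline_sd_rejected(self):
        panel = panel_from_scores({1: {0: 10.0}, 2: {0: 10.0}})
        with pytest.raises(ValueError, match="SD"):
            composite_z(panel)


class TestCostGLM:
    def test_intercept_only_fits_sample_mean(self, rng):
        y = rng.gamma(2.0, 500.0, 300)
        X = pd.DataFrame({"intercept": np.ones(300)})
        fit = fit_cost_glm(y, X)
        np.testing.assert_allclose(fit.fitted, y.mean(), rtol=1e-8)

    def test_nonpositive_costs_error_mentions_option(self, rng):
        y = np.concatenate([[0.0], rng.gamma(2.0, 500.0, 50)])
        X = pd.DataFrame({"intercept": np.ones(51)})
        with pytest.raises(ValueError, match="zero_offset"):
            fit_cost_glm(y, X)
        fit = fit_cost_glm(y, X, zero_offset=True)
        assert np.isfinite(fit.params).all()

    def test_saturated_arm_model_reproduces_arm_means(self, rng):
        """In an arm-only model the gamma GLM fitted means equal the
        observed arm means (IRLS identity)."""
        arm = np.repeat(ARMS, 100)
        mu = pd.Series(arm).map({"PFA+MI": 900, "PFA": 850, "MI": 870,
                                 "placebo": 800}).to_numpy(float)
        y = rng.gamma(2.0, mu / 2.0)
        X = pd.get_dummies(pd.DataFrame({"arm": pd.Categorical(
            arm, categories=list(ARMS))}), drop_first=True, dtype=float)
        X.insert(0, "intercept", 1.0)
        fit = fit_cost_glm(y, X)
        for a in ARMS:
            np.testing.assert_allclose(
                fit.fitted[arm == a].mean(), y[arm == a].mean(), rtol=1e-7)
            np.testing.assert_allclose(fit.marginal_arm_means()[a],
                                       y[arm == a].mean(), rtol=1e-7)

    def test_reference_rr_absent_and_rr_positive(self, rng):
        arm = np.repeat(ARMS, 50)
        y = rng.gamma(2.0, 400.0, 200)
        X = pd.get_dummies(pd.DataFrame({"arm": pd.Categorical(
            arm, categories=list(ARMS))}), drop_first=True, dtype=float)
        X.insert(0, "intercept", 1.0)
        fit = fit_cost_glm(y, X)
        assert "intercept" not in fit.rr_table.index
        assert (fit.rr_table["rr"] > 0).all()


@pytest.fixture(scope="module")
def null_trial():
    cfg = TrialConfig(n_per_arm=150, random_seed=21,
                      true_z_effects={a: 0.0 for a in ARMS})
    return generate_trial(cfg)


class TestMixedModel:
    def test_null_contrasts_within_3se(self, null_trial):
        comp = composite_z(null_trial.cognition)
        fit = fit_z_mixed(comp.panel, null_trial.participants,
                          center_mode="fixed")
        assert fit.converged
        assert (fit.contrasts["estimate"].abs()
                < 3 * fit.contrasts["se"]).all()

    def test_random_and_fixed_center_modes_agree(self, null_trial):
        comp = composite_z(null_trial.cognition)
        fx = fit_z_mixed(comp.panel, null_trial.participants,
                         center_mode="fixed")
        rd = fit_z_mixed(comp.panel, null_trial.participants,
                         center_mode="random")
        assert rd.center_mode == "random"
        assert rd.var_center is not None and rd.var_center >= 0
        np.testing.assert_allclose(rd.contrasts["estimate"].to_numpy(),
                                   fx.contrasts["estimate"].to_numpy(),
                                   atol=0.005)

    def test_contrasts_invariant_to_constant_shift(self, null_trial):
        comp = composite_z(null_trial.cognition)
        shifted = comp.panel.copy()
        shifted["z"] = shifted["z"] + 5.0
        a = fit_z_mixed(comp.panel, null_trial.participants,
                        center_mode="none")
        b = fit_z_mixed(shifted, null_trial.participants, center_mode="none")
        np.testing.assert_allclose(a.contrasts["estimate"].to_numpy(),
                                   b.contrasts["estimate"].to_numpy(),
                                   atol=1e-6)

    def test_variance_components_recovered(self):
        """Participant-intercept and residual variances recovered on a
        larger synthetic panel."""
        cfg = TrialConfig(n_per_arm=500, random_seed=23)
        ds = generate_trial(cfg)
        comp = composite_z(ds.cognition)
        fit = fit_z_mixed(comp.panel, ds.participants, center_mode="none")
        # composite-scale: subject var sb², occasion+test noise var
        sb2 = cfg.participant_intercept_sd ** 2
        resid = cfg.occasion_sd ** 2 + cfg.test_noise_sd ** 2 / 4
        assert fit.var_participant == pytest.approx(sb2, rel=0.15)
        assert fit.var_residual == pytest.approx(resid, rel=0.15)


class TestAdjustedIncrements:
    def test_null_arms_give_intervention_only_costs(self, rng):
        """With identical arms, ΔC reduces to the intervention cost
        difference and ΔE sits near zero."""
        cfg = TrialConfig(n_per_arm=250, random_seed=31,
                          true_z_effects={a: 0.0 for a in ARMS},
                          arm_cost_multipliers={a: 1.0 for a in ARMS})
        ds = generate_trial(cfg)
        from mapt_cea import cost_panel_for
        panel = cost_panel_for(ds)
        comp = composite_z(ds.cognition)
        parts = ds.participants.reset_index(drop=True)
        X = predictor_matrix(parts, baseline_z=comp.baseline)
        y = panel.totals["cumulative_3y_without_intervention"].reset_index(
            drop=True)
        mixed = fit_z_mixed(comp.panel, parts, center_mode="fixed")
        tt = TariffTable.from_config(cfg)
        inc = adjusted_increments(y, X, mixed, parts, tt)
        t = inc.table.set_index("arm")
        # ΔC(with) − ΔC(without) = intervention difference, exactly
        np.testing.assert_array_equal(
            (t["delta_c"] - t["delta_c_without"]).to_numpy(),
            t["intervention_diff"].to_numpy())
        # cost SE of an arm-mean difference at this n
        obs = y.to_numpy()
        se_c = np.nanstd(obs) * np.sqrt(2 / cfg.n_per_arm)
        assert (t["delta_c_without"].abs() < 4 * se_c).all()
        assert (t["delta_e"].abs()
                < 4 * mixed.contrasts["se"].to_numpy()).all()

    def test_arm_only_adjustment_equals_raw_differences(self, rng):
        """With no covariate effects in the design, marginal standardisation
        reproduces raw arm-mean differences."""
        n = 400
        arm = pd.Series(rng.choice(ARMS, n))
        y = rng.gamma(2.0, 400.0, n) + arm.map(
            {"PFA+MI": 300, "PFA": 100, "MI": 200, "placebo": 0}).to_numpy()
        X = pd.get_dummies(pd.DataFrame({"arm": pd.Categorical(
            arm, categories=list(ARMS))}), drop_first=True, dtype=float)
        X.insert(0, "intercept", 1.0)
        fit = fit_cost_glm(y, X)
        means = fit.marginal_arm_means()
        for a in ("PFA+MI", "PFA", "MI"):
            raw = y[(arm == a).to_numpy()].mean() - y[
                (arm == "placebo").to_numpy()].mean()
            assert means[a] - means["placebo"] == pytest.approx(raw, rel=1e-6)
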