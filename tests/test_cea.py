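"""ICER semantics, CE bootstrap, confidence ellipses, CEACs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mapt_cea import (bootstrap_ce, binary_effectiveness, ceac,
                      confidence_ellipse, icer)


class TestICER:
    @pytest.mark.parametrize("dc, de, ratio, quadrant", [
        (1986.0, 0.093, 21354.8, "NE"),
        (1237.0, 0.011, 112454.5, "NE"),
        (1705.0, 0.079, 21582.3, "NE"),
        (-100.0, 0.05, -2000.0, "dominant"),
        (500.0, -0.1, -5000.0, "dominated"),
        (-500.0, -0.1, 5000.0, "SW"),
    ])
    def test_ratio_and_quadrant(self, dc, de, ratio, quadrant):
        out = icer(dc, de)
        assert out.ratio == pytest.approx(ratio, abs=0.1)
        assert out.quadrant == quadrant
        assert out.defined
        assert out.caution == (quadrant == "SW")

    def test_zero_effect_flagged_not_raised(self):
        out = icer(100.0, 0.0)
        assert not out.defined
        assert np.isnan(out.ratio)
        assert out.quadrant == "undefined"

    @given(dc=st.floats(-1e6, 1e6), de=st.floats(-10, 10))
    @settings(max_examples=200, derandomize=True)
    def test_quadrant_consistent_with_signs(self, dc, de):
        out = icer(dc, de)
        if de == 0:
            assert not out.defined
        else:
            assert out.ratio == pytest.approx(dc / de, rel=1e-12)
            if de > 0:
                assert out.quadrant == ("NE" if dc >= 0 else "dominant")
            else:
                assert out.quadrant == ("dominated" if dc >= 0 else "SW")


def two_arm_frame(n, rng, cost_sd=1000.0, eff_sd=0.5):
    half = n // 2
    return pd.DataFrame({
        "arm": ["MI"] * half + ["placebo"] * half,
        "cost": np.concatenate([rng.normal(8000, cost_sd, half),
                                rng.normal(7000, cost_sd, half)]),
        "effect": np.concatenate([rng.normal(0.1, eff_sd, half),
                                  rng.normal(0.0, eff_sd, half)]),
    })


class TestBootstrap:
    def test_single_replicate_contract(self, rng):
        frame = two_arm_frame(40, rng)
        frame = pd.concat([frame, pd.DataFrame(
            {"arm": ["PFA", "PFA+MI"] * 10,
             "cost": 7000.0, "effect": 0.0})], ignore_index=True)
        reps = bootstrap_ce(frame, B=1, seed=0)
        assert len(reps.for_arm("MI")) == 1

    def test_degenerate_data_gives_point_mass(self):
        frame = pd.DataFrame({
            "arm": np.repeat(["PFA+MI", "PFA", "MI", "placebo"], 5),
            "cost": np.repeat([9171.0, 8500.0, 8765.0, 7106.0], 5),
            "effect": np.repeat([0.093, 0.011, 0.079, 0.0], 5)})
        reps = bootstrap_ce(frame, B=50, seed=1)
        mi = reps.for_arm("MI")
        np.testing.assert_allclose(mi["delta_c"].to_numpy(), 8765.0 - 7106.0)
        np.testing.assert_allclose(mi["delta_e"].to_numpy(), 0.079)

    def test_reproducible_from_seed(self, rng):
        frame = two_arm_frame(60, rng)
        frame = pd.concat([frame, pd.DataFrame(
            {"arm": ["PFA", "PFA+MI"] * 5, "cost": 7000.0, "effect": 0.0})],
            ignore_index=True)
        a = bootstrap_ce(frame, B=100, seed=3)
        b = bootstrap_ce(frame, B=100, seed=3)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_bootstrap_sd_matches_analytic_se(self):
        """Bootstrap SD of ΔE on a two-arm design approximates the
        closed-form SE of a difference of means."""
        rng = np.random.default_rng(12)
        n = 400
        frame = two_arm_frame(2 * n, rng, eff_sd=0.5)
        frame = pd.concat([frame, pd.DataFrame(
            {"arm": ["PFA", "PFA+MI"] * 5, "cost": 7000.0, "effect": 0.0})],
            ignore_index=True)
        reps = bootstrap_ce(frame, B=2000, seed=4)
        analytic = np.sqrt(0.5 ** 2 / n + 0.5 ** 2 / n)
        boot_sd = reps.for_arm("MI")["delta_e"].std()
        assert boot_sd == pytest.approx(analytic, rel=0.15)

    def test_intervention_costs_shift_delta_c(self, rng):
        frame = two_arm_frame(60, rng)
        frame = pd.concat([frame, pd.DataFrame(
            {"arm": ["PFA", "PFA+MI"] * 5, "cost": 7000.0, "effect": 0.0})],
            ignore_index=True)
        plain = bootstrap_ce(frame, B=50, seed=5)
        shifted = bootstrap_ce(frame, B=50, seed=5,
                               intervention_costs={"MI": 920.0})
        np.testing.assert_allclose(
            shifted.for_arm("MI")["delta_c"].to_numpy(),
            plain.for_arm("MI")["delta_c"].to_numpy() + 920.0)


class TestEllipse:
    def make_reps(self, pts, arm="MI"):
        return pd.DataFrame({"arm": arm, "b": np.arange(len(pts)),
                             "delta_e": pts[:, 0], "delta_c": pts[:, 1]})

    def test_radius_is_chi2_quantile(self, rng):
        pts = rng.multivariate_normal([0, 0], np.eye(2), 500)
        ell = confidence_ellipse(self.make_reps(pts), "MI", level=0.95)
        assert ell.radius2 == pytest.approx(5.9915, abs=1e-3)

    def test_known_bivariate_normal_coverage(self):
        rng = np.random.default_rng(2)
        cov = np.array([[0.002, 0.5], [0.5, 250_000.0]])
        pts = rng.multivariate_normal([0.09, 2000.0], cov, 20_000)
        ell = confidence_ellipse(self.make_reps(pts), "MI")
        inside = ell.contains(pts)
        assert inside.mean() == pytest.approx(0.95, abs=0.01)

    def test_identical_replicates_degenerate(self):
        pts = np.tile([0.05, 1000.0], (50, 1))
        ell = confidence_ellipse(self.make_reps(pts), "MI")
        assert ell.degenerate

    def test_order_invariance(self, rng):
        pts = rng.multivariate_normal([0.1, 1500.0],
                                      [[0.01, 0], [0, 10_000.0]], 300)
        a = confidence_ellipse(self.make_reps(pts), "MI")
        b = confidence_ellipse(self.make_reps(pts[::-1]), "MI")
        np.testing.assert_allclose(a.center, b.center)
        np.testing.assert_allclose(a.cov, b.cov, rtol=1e-10)

    def test_too_few_replicates_rejected(self, rng):
        pts = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            confidence_ellipse(self.make_reps(pts), "MI")


class TestCEAC:
    def make_reps(self, dc, de, arm="MI"):
        return pd.DataFrame({"arm": arm, "b": np.arange(len(dc)),
                             "delta_c": dc, "delta_e": de})

    def test_limit_cases_exact(self, rng):
        dc = rng.normal(100, 400, 1000)
        de = rng.normal(0.01, 0.05, 1000)
        reps = self.make_reps(dc, de)
        out = ceac(reps, "MI", wtp_grid=np.array([0.0, 1e9]))
        assert out.curve["probability"].iloc[0] == (dc < 0).mean()
        assert out.curve["probability"].iloc[1] == (de > 0).mean()

    def test_single_atom_steps_at_its_icer(self):
        reps = self.make_reps(np.full(100, 100.0), np.full(100, 0.01))
        grid = np.array([0.0, 9_999.0, 10_000.0, 10_001.0])
        out = ceac(reps, "MI", wtp_grid=grid)
        np.testing.assert_array_equal(
            out.curve["probability"].to_numpy(), [0.0, 0.0, 0.0, 1.0])

    def test_monotone_when_all_effects_positive(self, rng):
        dc = rng.normal(500, 300, 500)
        de = np.abs(rng.normal(0.05, 0.02, 500)) + 1e-6
        out = ceac(self.make_reps(dc, de), "MI")
        assert (np.diff(out.curve["probability"].to_numpy()) >= 0).all()
        assert out.curve["probability"].between(0, 1).all()

    def test_probability_at_point_icer_matches_ray_fraction(self, rng):
        dc = rng.normal(1000, 300, 2000)
        de = np.abs(rng.normal(0.05, 0.01, 2000))
        point = icer(dc.mean(), de.mean())
        out = ceac(self.make_reps(dc, de),
                   wtp_grid=np.array([point.ratio]))
        below_ray = ((point.ratio * de - dc) > 0).mean()
        assert out.curve["probability"].iloc[0] == pytest.approx(below_ray)

    def test_empty_grid_rejected(self, rng):
        reps = self.make_reps(np.ones(20), np.ones(20))
        with pytest.raises(ValueError):
            ceac(reps, "MI", wtp_grid=np.array([]))
        with pytest.raises(ValueError):
            ceac(reps, "MI", wtp_grid=np.array([-1.0]))


class TestBinaryEffectiveness:
    def test_examples(self):
        assert binary_effectiveness([0.0, -0.1, -0.29]) == 100.0
        assert binary_effectiveness([-0.31, 0.5]) == 50.0

    def test_boundary_counts_as_aggravation_by_default(self):
        assert binary_effectiveness([-0.3]) == 0.0
        assert binary_effectiveness([-0.3], strict=False) == 100.0

    def test_missing_dropped_and_all_missing_rejected(self):
        assert binary_effectiveness([np.nan, 0.0]) == 100.0
        with pytest.raises(ValueError):
            binary_effectiveness([np.nan, np.nan])

    def test_normal_cdf_oracle(self):
        """Changes ~ N(0, 0.5²): share above −0.3 tends to Φ(0.6) ≈ 72.6%."""
        rng = np.random.default_rng(9)
        x = rng.normal(0.0, 0.5, 20_000)
        expected = 100 * stats.norm.cdf(0.3 / 0.5)
        se = 100 * np.sqrt(0.726 * 0.274 / 20_000)
        assert abs(binary_effectiveness(x) - expected) < 3 * se
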