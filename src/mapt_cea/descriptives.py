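"""Group descriptives: BCa bootstrap CIs, rank tests, cost summary tables.

Three-year cumulative costs are summarised per arm as mean cost per
participant with bias-corrected and accelerated (BCa) bootstrap 95%
confidence intervals, restricted to participants with a complete follow-up;
between-arm differences are tested with a global nonparametric
Kruskal–Wallis test.  Baseline characteristics are compared with
Kruskal–Wallis (continuous) or chi-square (categorical) tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .costing import CostPanel
from .synthetic_trial import COGNITIVE_TESTS, TrialDataset


@dataclass(frozen=True)
class BCaInterval:
    mean: float
    lo: float
    hi: float
    degenerate: bool = False

    def astuple(self) -> tuple[float, float, float]:
        return (self.mean, self.lo, self.hi)


def bca_interval(values, B: int = 2000, alpha: float = 0.05,
                 seed: int | np.random.Generator = 0) -> BCaInterval:
    """BCa bootstrap confidence interval for the mean.

    The percentile interval is corrected for median bias,
    z0 = Φ⁻¹(#{θ*_b < θ̂}/B), and for skewness through the jackknife
    acceleration a = Σ(θ̄₍·₎ − θ₍ᵢ₎)³ / (6 [Σ(θ̄₍·₎ − θ₍ᵢ₎)²]^{3/2});
    the adjusted percentiles α₁, α₂ are then read off the bootstrap
    distribution of the mean.  A constant sample returns the degenerate
    interval (v, v, v) with ``degenerate=True`` (a is undefined there).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("BCa interval needs at least 2 observations")
    if B < 200:
        raise ValueError("B must be at least 200")
    theta = x.mean()
    if np.ptp(x) == 0.0:
        return BCaInterval(theta, theta, theta, degenerate=True)

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    boot = x[rng.integers(0, n, size=(B, n))].mean(axis=1)

    p0 = np.clip((boot < theta).mean(), 1.0 / (B + 1), B / (B + 1))
    z0 = stats.norm.ppf(p0)
    # jackknife means in closed form for the sample mean
    jack = (x.sum() - x) / (n - 1)
    d = jack.mean() - jack
    denom = (d ** 2).sum() ** 1.5
    a = (d ** 3).sum() / (6.0 * denom) if denom > 0 else 0.0

    z_lo, z_hi = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    a1 = stats.norm.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo)))
    a2 = stats.norm.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi)))
    lo, hi = np.quantile(boot, [a1, a2])
    return BCaInterval(theta, float(lo), float(hi))


def percentile_interval(values, B: int = 2000, alpha: float = 0.05,
                        seed: int | np.random.Generator = 0
                        ) -> BCaInterval:
    """Plain percentile bootstrap interval for the mean (reference method:
    BCa reduces to it when z0 = 0 and a = 0)."""
    x = np.asarray(values, dtype=float)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    boot = x[rng.integers(0, x.size, size=(B, x.size))].mean(axis=1)
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    return BCaInterval(x.mean(), float(lo), float(hi))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Global Kruskal–Wallis rank test across ≥2 groups.

    Returns (H, p) with mid-rank tie correction and a chi-square reference
    on k−1 degrees of freedom.  If every value is identical across groups
    the statistic is degenerate and (0.0, nan) is returned.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0.0:
        return (0.0, float("nan"))
    h, p = stats.kruskal(*groups)
    return (float(h), float(p))


def complete_cases(dataset: TrialDataset) -> pd.Series:
    """Boolean per participant: complete economic follow-up (all six
    half-year windows) and a completed final cognitive visit."""
    parts = dataset.participants.set_index("participant_id")
    econ_ok = ~parts.get("econ_missing", pd.Series(False, index=parts.index))
    final_month = max(dataset.config.visit_months)
    last = dataset.cognition[dataset.cognition["month"] == final_month]
    seen_final = last.set_index("participant_id")[list(COGNITIVE_TESTS)].notna().all(axis=1)
    cog_ok = seen_final.reindex(parts.index, fill_value=False)
    return (econ_ok & cog_ok).rename("complete_case")


@dataclass
class GroupSummary:
    """Arm × component cost table with BCa CIs plus global rank tests."""

    table: pd.DataFrame       # arm, component, freq_mean, cost_mean, cost_lo, cost_hi
    tests: pd.DataFrame       # component, kw_h, kw_p
    n_complete: pd.Series     # complete cases per arm

    def formatted(self) -> str:
        wide = self.table.pivot(index="component", columns="arm",
                                values="cost_mean").round(0)
        return wide.to_string()


def summarize_costs(panel: CostPanel, dataset: TrialDataset,
                    B: int = 2000, seed: int = 0,
                    restrict_complete: bool = True) -> GroupSummary:
    """Per-arm, per-component mean frequencies and costs with BCa 95% CIs
    over complete-follow-up participants, Kruskal–Wallis p per component,
    and both cumulative totals (with and without intervention)."""
    rng = np.random.default_rng(seed)
    parts = dataset.participants
    cc = complete_cases(dataset)
    keep = parts["participant_id"].map(cc) if restrict_complete else pd.Series(
        True, index=parts.index)
    parts = parts[keep.to_numpy(bool)]
    ids = parts["participant_id"]

    # per-participant 3-year component costs and event counts
    comp_costs = (panel.costs[panel.costs["participant_id"].isin(ids)]
                  .groupby(["participant_id", "component"])["cost"].sum()
                  .unstack(fill_value=0.0)
                  .reindex(ids, fill_value=0.0))
    counts = (dataset.events[dataset.events["participant_id"].isin(ids)]
              .groupby(["participant_id", "category"]).size()
              .unstack(fill_value=0)
              .reindex(ids, fill_value=0))
    totals = panel.totals.set_index("participant_id").loc[ids]
    comp_costs["intervention"] = totals["intervention_cost"]
    comp_costs["total_without_intervention"] = (
        totals["cumulative_3y_without_intervention"])
    comp_costs["total_with_intervention"] = (
        totals["cumulative_3y_with_intervention"])

    arm_of = parts.set_index("participant_id")["arm"]
    rows, test_rows = [], []
    for component in comp_costs.columns:
        by_arm = {a: comp_costs[component][arm_of == a].dropna().to_numpy()
                  for a in dataset.arms}
        usable = {a: v for a, v in by_arm.items() if v.size >= 2}
        if len(usable) == len(by_arm):
            h, p = kruskal_wallis(list(by_arm.values()))
        else:
            h, p = (float("nan"), float("nan"))
        test_rows.append({"component": component, "kw_h": h, "kw_p": p})
        for arm, v in by_arm.items():
            if v.size < 2:
                rows.append({"arm": arm, "component": component,
                             "freq_mean": np.nan, "cost_mean": np.nan,
                             "cost_lo": np.nan, "cost_hi": np.nan,
                             "available": False})
                continue
            ci = bca_interval(v, B=B, seed=rng)
            freq = (counts.loc[arm_of[arm_of == arm].index, component].mean()
                    if component in counts.columns else np.nan)
            rows.append({"arm": arm, "component": component,
                         "freq_mean": freq, "cost_mean": ci.mean,
                         "cost_lo": ci.lo, "cost_hi": ci.hi,
                         "available": True})
    n_complete = arm_of.value_counts().reindex(list(dataset.arms), fill_value=0)
    return GroupSummary(table=pd.DataFrame(rows),
                        tests=pd.DataFrame(test_rows),
                        n_complete=n_complete)


def annualized(cumulative_3y: float) -> float:
    """Annualised cost over the 3-year horizon (cumulative / 3)."""
    return cumulative_3y / 3.0


def baseline_table(dataset: TrialDataset) -> pd.DataFrame:
    """Baseline characteristics per arm with Kruskal–Wallis (continuous) or
    chi-square (categorical) global p-values."""
    parts = dataset.participants
    arms = list(dataset.arms)
    rows = []

    def kw_row(name, col):
        groups = [parts.loc[parts["arm"] == a, col].to_numpy(float)
                  for a in arms]
        _, p = kruskal_wallis(groups)
        row = {"characteristic": name, "test": "kruskal-wallis", "p": p}
        for a, g in zip(arms, groups):
            row[a] = f"{np.mean(g):.1f} ({np.std(g, ddof=1):.1f})"
        rows.append(row)

    def chi2_row(name, col):
        tab = pd.crosstab(parts[col], parts["arm"]).reindex(columns=arms)
        chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy())
        row = {"characteristic": name, "test": "chi-square", "p": p}
        for a in arms:
            top = tab[a].idxmax()
            row[a] = f"{tab[a].sum()} (mode {top})"
        rows.append(row)

    kw_row("age_years", "age_years")
    chi2_row("gender_male", "male")
    chi2_row("frailty", "frailty")
    chi2_row("education", "education")
    kw_row("n_medical_conditions", "n_medical_conditions")
    return pd.DataFrame(rows)
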