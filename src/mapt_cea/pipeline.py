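"""End-to-end pipeline: generate → cost → summarize → impute → adjust → CEA.

Runs the whole trial-based cost-effectiveness analysis as a configured,
seeded sequence of stages and collects the tables a trial report needs:
baseline characteristics, per-arm cost breakdown with BCa CIs, gamma-GLM
relative-risk table, adjusted increments, ICERs, CE-plane replicate clouds
with confidence ellipses, and CEACs.  The base case imputes missing
cumulative costs (PMM multiple imputation); the sensitivity analysis
restricts every stage to participants with complete follow-up.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjustment import (AdjustedIncrements, MixedFit, adjusted_increments,
                         composite_z, fit_cost_glm, fit_z_mixed)
from .cea import (CEAC, CEReplicates, DEFAULT_WTP, Ellipse, ICER,
                  binary_effectiveness, bootstrap_ce, ceac,
                  confidence_ellipse, icer)
from .costing import CostPanel, TariffTable, cost_panel_for, intervention_cost
from .descriptives import GroupSummary, baseline_table, complete_cases, summarize_costs
from .imputation import (CompletedDatasets, ImputationSpec, attrition_check,
                         pmm_impute, predictor_matrix, rubin_pool_vector)
from .synthetic_trial import (ARMS, TrialConfig, TrialDataset,
                              apply_missingness, generate_trial)

logger = logging.getLogger("mapt_cea")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``mode`` selects the base case (``"imputed"``) or the complete-follow-up
    sensitivity analysis (``"complete_case"``); ``effect_unit`` selects
    Z-score points (``"z"``) or the percentage of participants without a
    clinically significant (0.3-point) cognitive decline (``"binary"``).
    """

    trial: TrialConfig = field(default_factory=TrialConfig)
    tariffs: TariffTable | None = None
    mode: str = "imputed"
    effect_unit: str = "z"
    B: int = 1000
    m: int = 20
    k_donors: int = 5
    summary_B: int = 1000
    wtp_grid: np.ndarray | None = None
    seed: int = 0
    aggravation_cutoff: float = -0.3
    center_mode: str = "random"

    def validate(self) -> None:
        if self.mode not in ("imputed", "complete_case"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.effect_unit not in ("z", "binary"):
            raise ValueError(f"unknown effect_unit {self.effect_unit!r}")
        if self.B < 1:
            raise ValueError("B must be positive")


@dataclass
class PipelineResult:
    """Report bundle of one pipeline run."""

    dataset: TrialDataset
    panel: CostPanel
    baseline: pd.DataFrame
    cost_summary: GroupSummary
    completed: CompletedDatasets | None
    mixed: MixedFit
    rr_with: pd.DataFrame
    rr_without: pd.DataFrame
    increments: AdjustedIncrements
    icers: dict[str, ICER]
    replicates: CEReplicates
    ellipses: dict[str, Ellipse]
    ceacs: dict[str, CEAC]
    attrition: object | None
    no_aggravation_pct: dict[str, float]
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        """Emit all report tables as CSV plus the JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.baseline.to_csv(out / "table1_baseline.csv", index=False)
        self.cost_summary.table.to_csv(out / "table2_costs.csv", index=False)
        self.cost_summary.tests.to_csv(out / "table2_tests.csv", index=False)
        self.rr_with.to_csv(out / "table3_rr_with_intervention.csv")
        self.rr_without.to_csv(out / "table3_rr_without_intervention.csv")
        self.increments.table.to_csv(out / "adjusted_increments.csv",
                                     index=False)
        self.replicates.to_csv(out / "ce_replicates.csv")
        for arm, ell in self.ellipses.items():
            pd.DataFrame(ell.polygon, columns=["delta_e", "delta_c"]).to_csv(
                out / f"ellipse_{arm.replace('+', '_')}.csv", index=False)
        for arm, c in self.ceacs.items():
            c.curve.to_csv(out / f"ceac_{arm.replace('+', '_')}.csv",
                           index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Execute the full seeded pipeline and return the report bundle."""
    config = config or PipelineConfig()
    config.validate()
    seed = int(config.seed)
    trial_cfg = dataclasses.replace(config.trial, random_seed=seed)
    tariffs = config.tariffs or TariffTable.from_config(trial_cfg)

    logger.info("stage generate: %d participants, 4 arms",
                trial_cfg.n_per_arm * 4)
    complete = generate_trial(trial_cfg)
    dataset = apply_missingness(complete, trial_cfg)
    cc = complete_cases(dataset)
    logger.info("stage missingness: %d/%d complete cases",
                int(cc.sum()), len(cc))

    logger.info("stage cost: valuing %d events", len(dataset.events))
    panel = cost_panel_for(dataset, tariffs, seed=seed + 1_000_001)

    baseline = baseline_table(dataset)
    summary = summarize_costs(panel, dataset, B=config.summary_B,
                              seed=seed + 1_000_002)

    comp = composite_z(dataset.cognition)
    parts = dataset.participants.reset_index(drop=True)
    X = predictor_matrix(parts)
    X_z = predictor_matrix(parts, baseline_z=comp.baseline)

    costs_without = panel.totals.set_index("participant_id")[
        "cumulative_3y_without_intervention"].reindex(
        parts["participant_id"]).reset_index(drop=True)

    if config.mode == "imputed":
        sel = np.ones(len(parts), dtype=bool)
    else:
        sel = parts["participant_id"].map(cc).to_numpy(bool)
    parts_a = parts[sel].reset_index(drop=True)
    X_a = X[sel].reset_index(drop=True)
    X_z_a = X_z[sel].reset_index(drop=True)
    y_a = costs_without[sel].reset_index(drop=True)

    attrition = None
    if config.mode == "imputed":
        spec = ImputationSpec(m=config.m, k_donors=config.k_donors,
                              seed=seed + 1_000_003)
        logger.info("stage impute: %d missing of %d, m=%d",
                    int(y_a.isna().sum()), len(y_a), spec.m)
        completed = pmm_impute(y_a, X_a, spec)
        # attrition-bias check: complete-case GLM vs Rubin-pooled MI GLM
        obs = ~completed.imputed_mask
        fit_cc = fit_cost_glm(y_a[obs].to_numpy(), X_a[obs])
        stack_q, stack_v = [], []
        for j in range(completed.m):
            f = fit_cost_glm(completed.column(j), X_a)
            stack_q.append(f.params.to_numpy())
            stack_v.append(f.cov.to_numpy())
        qbar, vbar = rubin_pool_vector(np.array(stack_q), np.array(stack_v))
        attrition = attrition_check(fit_cc.params.to_numpy(), qbar,
                                    fit_cc.cov.to_numpy(), vbar)
        logger.info("stage impute: attrition check chi2=%.2f p=%.3f",
                    attrition.statistic, attrition.pvalue)
    else:
        completed = None
        obs = y_a.notna().to_numpy()
        y_a = y_a.where(pd.Series(obs), np.nan)

    logger.info("stage adjust: mixed model (%s centers) + gamma GLM",
                config.center_mode)
    cog = dataset.cognition
    if config.mode == "complete_case":
        keep_ids = set(parts_a["participant_id"])
        cog = cog[cog["participant_id"].isin(keep_ids)]
    mixed = fit_z_mixed(comp.panel[comp.panel["participant_id"].isin(
        set(parts_a["participant_id"]))], parts_a,
        center_mode=config.center_mode)

    cost_input = completed if completed is not None else y_a
    increments = adjusted_increments(cost_input, X_z_a, mixed, parts_a,
                                     tariffs)

    # Table-3-like relative-risk tables (first completed dataset)
    y_rr = (completed.column(0) if completed is not None
            else y_a.to_numpy(float))
    interv = parts_a["arm"].map(
        lambda a: intervention_cost(a, tariffs)).to_numpy(float)
    rr_without = fit_cost_glm(y_rr, X_z_a).rr_table
    rr_with = fit_cost_glm(y_rr + interv, X_z_a).rr_table

    # effectiveness in the chosen unit
    change = parts_a["participant_id"].map(comp.change_36m)
    no_aggr = {}
    for arm in ARMS:
        vals = change[parts_a["arm"] == arm]
        no_aggr[arm] = (binary_effectiveness(vals, config.aggravation_cutoff)
                        if vals.notna().any() else float("nan"))

    if config.effect_unit == "z":
        effect = change.to_numpy(float)
    else:
        ch = change.to_numpy(float)
        effect = np.where(np.isnan(ch), np.nan,
                          100.0 * (ch > config.aggravation_cutoff))

    icosts = {a: intervention_cost(a, tariffs) for a in ARMS}
    if completed is not None:
        frames = [pd.DataFrame({"arm": parts_a["arm"],
                                "cost": completed.column(j),
                                "effect": effect})
                  for j in range(completed.m)]
    else:
        frames = pd.DataFrame({"arm": parts_a["arm"],
                               "cost": y_a.to_numpy(float),
                               "effect": effect})
    logger.info("stage cea: bootstrap B=%d (%s)", config.B,
                config.effect_unit)
    reps = bootstrap_ce(frames, B=config.B, seed=seed + 1_000_004,
                        effect_unit=config.effect_unit,
                        intervention_costs=icosts)

    icers, ellipses, ceacs = {}, {}, {}
    for arm in [a for a in ARMS if a != "placebo"]:
        if config.effect_unit == "z":
            row = increments.table.set_index("arm").loc[arm]
            icers[arm] = icer(float(row["delta_c"]), float(row["delta_e"]))
        else:
            dc = float(increments.table.set_index("arm").loc[arm, "delta_c"])
            de = no_aggr[arm] - no_aggr["placebo"]
            icers[arm] = icer(dc, de)
        ellipses[arm] = confidence_ellipse(reps, arm)
        ceacs[arm] = ceac(reps, arm, wtp_grid=config.wtp_grid)

    manifest = {
        "package_version": __version__,
        "mode": config.mode,
        "effect_unit": config.effect_unit,
        "seeds": {"master": seed, "trial": seed, "costing": seed + 1_000_001,
                  "summary": seed + 1_000_002, "imputation": seed + 1_000_003,
                  "bootstrap": seed + 1_000_004},
        "n_participants": int(len(parts)),
        "n_analysis": int(len(parts_a)),
        "n_complete_cases": int(cc.sum()),
        "B": config.B,
        "m": config.m if config.mode == "imputed" else None,
        "intervention_costs": {a: icosts[a] for a in ARMS},
        "adjusted_increments": {
            r["arm"]: {"delta_c": r["delta_c"], "delta_e": r["delta_e"]}
            for r in increments.table.to_dict("records")},
        "icers": {a: {"ratio": icers[a].ratio, "quadrant": icers[a].quadrant}
                  for a in icers},
        "ceac_at_50000": {a: ceacs[a].at_reference for a in ceacs},
        "no_aggravation_pct": no_aggr,
        "attrition_check": (None if attrition is None else
                            {"statistic": attrition.statistic,
                             "pvalue": attrition.pvalue,
                             "df": attrition.df}),
        "rounded_totals": {
            a: _round_half_up(
                summary.table.set_index(["arm", "component"])
                .loc[(a, "total_with_intervention"), "cost_mean"])
            for a in ARMS
            if not np.isnan(summary.table.set_index(["arm", "component"])
                            .loc[(a, "total_with_intervention"), "cost_mean"])},
    }
    return PipelineResult(
        dataset=dataset, panel=panel, baseline=baseline,
        cost_summary=summary, completed=completed, mixed=mixed,
        rr_with=rr_with, rr_without=rr_without, increments=increments,
        icers=icers, replicates=reps, ellipses=ellipses, ceacs=ceacs,
        attrition=attrition, no_aggravation_pct=no_aggr, manifest=manifest)
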