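"""Covariate-adjusted cost and effectiveness estimation.

Effectiveness: the primary outcome is the change from baseline to 36
months in a composite Z score averaging four cognitive tests (free/total
recall of the FCSRT, ten MMSE orientation items, the Digit Symbol
Substitution Test, and 2-minute category fluency), each standardised to
the baseline cohort mean and SD.  Trajectories are smoothed by a linear
mixed model with fixed effects for intervention group, visit and their
interaction and random intercepts for center and participant; the adjusted
effect ΔE of each arm is its 36-month contrast versus placebo.

Costs: 3-year cumulative totals are modelled with a gamma GLM (log link)
on the analysis-plan covariates; adjusted cost increments ΔC versus
placebo come from marginal standardisation of the fitted model (predicting
every participant under each counterfactual arm), pooled over multiply
imputed datasets by Rubin's rules, with deterministic intervention costs
added on top so that cost additivity is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .costing import intervention_cost, TariffTable
from .imputation import CompletedDatasets, predictor_matrix
from .synthetic_trial import ARMS, COGNITIVE_TESTS, TrialDataset


@dataclass
class CompositeZ:
    """Composite cognitive Z scores per participant × visit."""

    panel: pd.DataFrame          # participant_id, month, z
    change_36m: pd.Series        # z(36) − z(0), indexed by participant_id
    baseline: pd.Series          # z(0), indexed by participant_id
    scales: pd.DataFrame         # per-test baseline mean and SD used


def composite_z(cognition: pd.DataFrame, baseline_month: int = 0,
                final_month: int = 36) -> CompositeZ:
    """Standardise each cognitive test to the baseline cohort mean/SD,
    average the four standardised scores, and compute 36-month change.

    The composite is missing whenever any of the four components is
    missing at that visit.
    """
    base = cognition[cognition["month"] == baseline_month]
    if base.empty:
        raise ValueError("no baseline visit in the cognitive panel")
    mu = base[list(COGNITIVE_TESTS)].mean()
    sd = base[list(COGNITIVE_TESTS)].std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero baseline SD for test(s) {list(zero.index)}")
    zcols = (cognition[list(COGNITIVE_TESTS)] - mu) / sd
    panel = cognition[["participant_id", "month"]].copy()
    panel["z"] = zcols.mean(axis=1, skipna=False)
    wide = panel.pivot(index="participant_id", columns="month", values="z")
    change = (wide[final_month] - wide[baseline_month]).rename("change_36m")
    scales = pd.DataFrame({"mean": mu, "sd": sd})
    return CompositeZ(panel=panel, change_36m=change,
                      baseline=wide[baseline_month].rename("baseline_z"),
                      scales=scales)


@dataclass
class GLMFit:
    """Fitted gamma/log GLM of cumulative costs.

    ``rr_table`` reports exp(coefficients) as relative risks with 95% Wald
    intervals; reference categories are implicit (RR ≡ 1).
    """

    params: pd.Series
    cov: pd.DataFrame
    rr_table: pd.DataFrame
    fitted: np.ndarray
    design: pd.DataFrame
    scale: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.exp(X.to_numpy(float) @ self.params.to_numpy())

    def marginal_arm_means(self, arms=ARMS) -> pd.Series:
        """Marginal standardisation: mean predicted cost with every
        participant assigned counterfactually to each arm."""
        arm_cols = [c for c in self.design.columns if c.startswith("arm_")]
        out = {}
        for arm in arms:
            X = self.design.copy()
            X[arm_cols] = 0.0
            if f"arm_{arm}" in arm_cols:
                X[f"arm_{arm}"] = 1.0
            out[arm] = float(self.predict(X).mean())
        return pd.Series(out)


def fit_cost_glm(costs, covariates: pd.DataFrame,
                 zero_offset: bool = False) -> GLMFit:
    """Fit a gamma GLM with log link to cumulative costs.

    Costs must be strictly positive; zero totals can be shifted by half the
    smallest positive observed cost with ``zero_offset=True``.
    """
    y = np.asarray(costs, dtype=float)
    if len(covariates) != y.size:
        raise ValueError("covariates and costs have mismatched lengths")
    keep = ~np.isnan(y)
    y = y[keep]
    X = covariates[keep]
    if (y <= 0).any():
        if not zero_offset:
            raise ValueError(
                "non-positive costs cannot enter a gamma/log GLM; pass "
                "zero_offset=True to shift zeros by half the smallest "
                "positive observed cost")
        shift = 0.5 * y[y > 0].min()
        y = np.where(y <= 0, y + shift, y)
    model = sm.GLM(y, X.to_numpy(float),
                   family=sm.families.Gamma(link=sm.families.links.Log()))
    try:
        res = model.fit(tol=1e-8)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular design in cost GLM: {err}") from err
    names = list(X.columns)
    params = pd.Series(res.params, index=names)
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    se = np.sqrt(np.diag(cov))
    zcrit = stats.norm.ppf(0.975)
    rr = pd.DataFrame({
        "rr": np.exp(params),
        "ci_lo": np.exp(params - zcrit * se),
        "ci_hi": np.exp(params + zcrit * se),
        "p": 2 * stats.norm.sf(np.abs(params / se)),
    })
    return GLMFit(params=params, cov=cov, rr_table=rr.drop(index="intercept"),
                  fitted=res.fittedvalues, design=X.reset_index(drop=True),
                  scale=float(res.scale))


@dataclass
class MixedFit:
    """Linear mixed model of the composite-Z trajectory."""

    contrasts: pd.DataFrame      # arm, estimate, se, ci_lo, ci_hi (36-month vs placebo)
    fe_params: pd.Series
    converged: bool
    center_mode: str             # "random", "fixed" or "none"
    var_participant: float
    var_center: float | None
    var_residual: float


def _mixed_contrasts(res, arms, final_month: int) -> pd.DataFrame:
    names = list(res.model.exog_names)
    fe = res.fe_params
    cov = np.asarray(res.cov_params())[:len(names), :len(names)]
    rows = []
    zcrit = stats.norm.ppf(0.975)
    for arm in arms:
        if arm == "placebo":
            continue
        # the 36-month change-from-baseline contrast vs placebo is the
        # arm × final-visit interaction (baseline differences are absorbed
        # by the arm main effect under randomisation)
        vec = np.zeros(len(names))
        for i, nm in enumerate(names):
            if nm == (f"C(arm, Treatment('placebo'))[T.{arm}]"
                      f":C(month)[T.{final_month}]"):
                vec[i] = 1.0
        est = float(vec @ fe)
        se = float(np.sqrt(vec @ cov @ vec))
        rows.append({"arm": arm, "estimate": est, "se": se,
                     "ci_lo": est - zcrit * se, "ci_hi": est + zcrit * se})
    return pd.DataFrame(rows)


def fit_z_mixed(z_panel: pd.DataFrame, participants: pd.DataFrame,
                center_mode: str = "random", final_month: int = 36) -> MixedFit:
    """Fit the trajectory model z ~ arm * visit with participant (and
    center) intercepts by maximum likelihood, and return the adjusted
    36-month arm-versus-placebo contrasts.

    ``center_mode`` controls the center term: ``"random"`` adds a center
    random intercept via a variance component (the fully specified model),
    ``"fixed"`` absorbs centers as fixed effects (fast, equivalent
    arm contrasts in a balanced design), ``"none"`` drops it.  If the
    random-center fit fails or its variance collapses to the boundary, the
    model falls back to ``"fixed"`` and flags it.
    """
    data = z_panel.merge(
        participants[["participant_id", "arm", "center_id"]],
        on="participant_id")
    data = data.dropna(subset=["z"]).copy()
    data["month"] = data["month"].astype(int)
    base = "z ~ C(arm, Treatment('placebo')) * C(month)"

    def _fit(mode: str):
        import statsmodels.formula.api as smf
        if mode == "random":
            model = smf.mixedlm(base, data, groups="center_id",
                                re_formula="1",
                                vc_formula={"participant":
                                            "0 + C(participant_id)"})
        elif mode == "fixed":
            model = smf.mixedlm(base + " + C(center_id)", data,
                                groups="participant_id", re_formula="1")
        elif mode == "none":
            model = smf.mixedlm(base, data, groups="participant_id",
                                re_formula="1")
        else:
            raise ValueError(f"unknown center_mode {mode!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=False, method="lbfgs", maxiter=200)

    mode = center_mode
    try:
        res = _fit(mode)
        ok = res.converged
    except (np.linalg.LinAlgError, ValueError):
        ok = False
        res = None
    if not ok and mode == "random":
        mode = "fixed"
        res = _fit(mode)
    if res is None or not res.converged:
        # final fallback: drop the center term entirely
        mode = "none"
        res = _fit(mode)

    if mode == "random":
        var_center = float(res.cov_re.iloc[0, 0])
        var_part = float(res.vcomp[0])
    else:
        var_center = None
        var_part = float(res.cov_re.iloc[0, 0])
    contrasts = _mixed_contrasts(res, participants["arm"].unique().tolist()
                                 if "placebo" in set(participants["arm"])
                                 else list(ARMS), final_month)
    order = [a for a in ARMS if a != "placebo"]
    contrasts = (contrasts.set_index("arm").reindex(order)
                 .reset_index())
    return MixedFit(contrasts=contrasts,
                    fe_params=pd.Series(res.fe_params,
                                        index=res.model.exog_names),
                    converged=bool(res.converged), center_mode=mode,
                    var_participant=var_part, var_center=var_center,
                    var_residual=float(res.scale))


@dataclass
class AdjustedIncrements:
    """Adjusted per-arm increments versus placebo."""

    table: pd.DataFrame          # arm, delta_c, delta_e, delta_c_without, intervention_diff
    per_imputation: pd.DataFrame  # imputation × arm ΔC (without intervention)


def adjusted_increments(completed: CompletedDatasets | pd.Series,
                        covariates: pd.DataFrame,
                        mixed: MixedFit,
                        participants: pd.DataFrame,
                        tariffs: TariffTable,
                        mode: str = "marginal",
                        zero_offset: bool = False) -> AdjustedIncrements:
    """Pooled adjusted (ΔC, ΔE) per intervention arm versus placebo.

    ``completed`` holds 3-year cumulative totals *without* intervention
    (one column per imputation, or a single complete-case series); per
    imputation a gamma GLM is fitted and per-arm increments derived by
    marginal standardisation (``mode="marginal"``) or by arm means of
    fitted values (``mode="fitted"``), then pooled across imputations.
    Deterministic intervention cost differences are added so that
    ΔC(with) − ΔC(without) equals the intervention cost difference exactly.
    """
    if isinstance(completed, CompletedDatasets):
        columns = [completed.column(j) for j in range(completed.m)]
    else:
        columns = [np.asarray(completed, dtype=float)]
    arm_series = participants["arm"].reset_index(drop=True)
    rows = []
    for j, y in enumerate(columns):
        fit = fit_cost_glm(y, covariates, zero_offset=zero_offset)
        if mode == "marginal":
            means = fit.marginal_arm_means()
        elif mode == "fitted":
            means = pd.Series({a: fit.fitted[arm_series.to_numpy() == a].mean()
                               for a in ARMS})
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for arm in ARMS:
            if arm != "placebo":
                rows.append({"imputation": j + 1, "arm": arm,
                             "delta_c_without": means[arm] - means["placebo"]})
    per_imp = pd.DataFrame(rows)
    pooled = per_imp.groupby("arm")["delta_c_without"].mean()

    out = []
    for arm in [a for a in ARMS if a != "placebo"]:
        idiff = intervention_cost(arm, tariffs) - intervention_cost(
            "placebo", tariffs)
        de = mixed.contrasts.set_index("arm").loc[arm, "estimate"]
        out.append({"arm": arm,
                    "delta_c_without": float(pooled[arm]),
                    "intervention_diff": idiff,
                    "delta_c": float(pooled[arm]) + idiff,
                    "delta_e": float(de)})
    return AdjustedIncrements(table=pd.DataFrame(out),
                              per_imputation=per_imp)
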