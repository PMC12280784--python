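"""Multiple imputation of missing 3-year cumulative costs.

Missing cumulative cost totals (assumed missing at random) are filled by
predictive mean matching (PMM): per imputation, regression coefficients are
drawn from their approximate Bayesian posterior, predictions are formed for
every participant, and each missing case borrows the observed value of a
donor drawn uniformly from the ``k`` observed cases with nearest
predictions.  PMM therefore never extrapolates beyond the observed support.
Imputation predictors follow the trial's analysis plan: age tercile,
gender, intervention arm, frailty level and medical-history-count tercile.

Pooling across imputations follows Rubin's rules with Barnard–Rubin
degrees of freedom, and a Hausman-type quadratic form compares the
complete-case and imputation-based estimators to flag attrition bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_trial import _tercile

DEFAULT_PREDICTORS = ("age_tercile", "male", "arm", "frailty",
                      "conditions_tercile")


@dataclass(frozen=True)
class ImputationSpec:
    """PMM settings: ``m`` imputed datasets, ``k_donors`` donor-pool size."""

    m: int = 20
    k_donors: int = 5
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise ValueError("m must be at least 2")
        if self.k_donors < 1:
            raise ValueError("k_donors must be at least 1")


def predictor_matrix(participants: pd.DataFrame,
                     baseline_z: pd.Series | None = None) -> pd.DataFrame:
    """Design matrix of the analysis-plan covariates (dummy-coded, with
    intercept): age terciles, gender, arm, frailty, medical-history-count
    terciles, optionally baseline composite-Z terciles.

    Terciles are computed on the observed marginal distribution with ties
    assigned to the lower tercile.
    """
    parts = participants
    df = pd.DataFrame(index=parts.index)
    df["age_tercile"] = _tercile(parts["age_years"].to_numpy(float))
    df["male"] = parts["male"].to_numpy(int)
    df["arm"] = parts["arm"].to_numpy()
    df["frailty"] = parts["frailty"].to_numpy()
    df["conditions_tercile"] = _tercile(
        parts["n_medical_conditions"].to_numpy(float))
    if baseline_z is not None:
        z0 = parts["participant_id"].map(baseline_z).to_numpy(float)
        df["baseline_z_tercile"] = _tercile(z0)
    # reference categories: youngest tercile, placebo, robust, lowest terciles
    df["arm"] = pd.Categorical(df["arm"],
                               categories=["placebo", "PFA", "MI", "PFA+MI"])
    df["frailty"] = pd.Categorical(df["frailty"],
                                   categories=["robust", "pre-frail", "frail"])
    for col in ("age_tercile", "conditions_tercile", "baseline_z_tercile"):
        if col in df:
            df[col] = pd.Categorical(df[col], categories=[0, 1, 2])
    X = pd.get_dummies(df, drop_first=True, dtype=float)
    X.insert(0, "intercept", 1.0)
    return X


@dataclass
class CompletedDatasets:
    """``m`` completed copies of the cost outcome plus provenance flags."""

    completed: pd.DataFrame       # columns imp_1..imp_m, index participant order
    imputed_mask: np.ndarray      # True where the original value was missing
    spec: ImputationSpec

    @property
    def m(self) -> int:
        return self.spec.m

    def column(self, j: int) -> np.ndarray:
        return self.completed.iloc[:, j].to_numpy(float)

    def to_long(self) -> pd.DataFrame:
        long = self.completed.reset_index(names="row").melt(
            id_vars="row", var_name="imputation", value_name="cost")
        long["imputation"] = long["imputation"].str.removeprefix(
            "imp_").astype(int)
        return long


def pmm_impute(costs: pd.Series | np.ndarray, covariates: pd.DataFrame,
               spec: ImputationSpec | None = None) -> CompletedDatasets:
    """Predictive-mean-matching multiple imputation of a single outcome.

    Per imputation: σ² is drawn from its scaled inverse chi-square
    posterior and β from N(β̂, σ²(XᵀX)⁻¹); predictions under the drawn β
    for the missing cases are matched to the ``k_donors`` observed cases
    with nearest predictions under β̂, and the fill value is a uniformly
    drawn donor's observed outcome.
    """
    spec = spec or ImputationSpec()
    spec.validate()
    y = np.asarray(costs, dtype=float)
    X = covariates.to_numpy(float)
    if X.shape[0] != y.size:
        raise ValueError("covariates and outcome lengths differ")
    if np.isnan(X).any():
        raise ValueError("covariates must be complete")
    miss = np.isnan(y)
    n_obs, k = (~miss).sum(), X.shape[1]
    if n_obs < k + spec.k_donors:
        raise ValueError(
            f"too few observed cases ({n_obs}) for {k} predictors "
            f"plus a donor pool of {spec.k_donors}")

    rng = np.random.default_rng(spec.seed)
    cols = {}
    if not miss.any():
        for j in range(spec.m):
            cols[f"imp_{j + 1}"] = y.copy()
    else:
        Xo, yo = X[~miss], y[~miss]
        XtX = Xo.T @ Xo
        XtX_inv = np.linalg.pinv(XtX)
        beta_hat = XtX_inv @ Xo.T @ yo
        resid = yo - Xo @ beta_hat
        df_res = max(n_obs - k, 1)
        sse = float(resid @ resid)
        pred_obs = Xo @ beta_hat
        L = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(k))
        for j in range(spec.m):
            sigma2 = sse / rng.chisquare(df_res)
            beta_star = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(k))
            pred_mis = X[miss] @ beta_star
            # k nearest observed predictions per missing case
            order = np.argsort(np.abs(pred_obs[None, :] - pred_mis[:, None]),
                               axis=1)[:, :spec.k_donors]
            pick = rng.integers(0, spec.k_donors, size=order.shape[0])
            donors = order[np.arange(order.shape[0]), pick]
            filled = y.copy()
            filled[miss] = yo[donors]
            cols[f"imp_{j + 1}"] = filled
    completed = pd.DataFrame(cols)
    if isinstance(costs, pd.Series):
        completed.index = costs.index
    return CompletedDatasets(completed=completed, imputed_mask=miss, spec=spec)


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    variance: float
    ci_lo: float
    ci_hi: float
    df: float
    between_variance: float
    within_variance: float


def rubin_pool(estimates, variances, alpha: float = 0.05) -> PooledEstimate:
    """Rubin's rules: pooled mean, total variance W + (1+1/m)B, and a t
    confidence interval on Barnard–Rubin degrees of freedom."""
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    if q.shape != w.shape:
        raise ValueError("estimates and variances have mismatched lengths")
    m = q.size
    if m < 2:
        raise ValueError("pooling needs at least 2 imputations")
    qbar = q.mean()
    W = w.mean()
    B = q.var(ddof=1)
    T = W + (1.0 + 1.0 / m) * B
    if B > 0:
        r = (1.0 + 1.0 / m) * B / W if W > 0 else np.inf
        df = (m - 1) * (1.0 + 1.0 / r) ** 2 if np.isfinite(r) else m - 1.0
    else:
        df = np.inf
    tcrit = stats.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else stats.norm.ppf(
        1 - alpha / 2)
    half = tcrit * np.sqrt(T)
    return PooledEstimate(float(qbar), float(T), float(qbar - half),
                          float(qbar + half), float(df), float(B), float(W))


def rubin_pool_vector(estimates: np.ndarray, covariances: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Vector version of Rubin's rules: pooled coefficient vector and total
    covariance W̄ + (1+1/m)B for an m × p stack of estimates."""
    Q = np.asarray(estimates, dtype=float)
    V = np.asarray(covariances, dtype=float)
    m = Q.shape[0]
    qbar = Q.mean(axis=0)
    W = V.mean(axis=0)
    dev = Q - qbar
    B = dev.T @ dev / (m - 1)
    return qbar, W + (1.0 + 1.0 / m) * B


@dataclass(frozen=True)
class AttritionCheck:
    statistic: float
    pvalue: float
    df: int
    generalized_inverse: bool


def attrition_check(complete_case_estimates, imputed_estimates,
                    complete_case_cov, imputed_cov) -> AttritionCheck:
    """Hausman-type attrition-bias check.

    Under MAR both estimators are consistent and the quadratic form
    dᵀ(ΔV)⁻d (d the estimate difference, ΔV the covariance difference of
    the less-efficient complete-case estimator versus the imputation-based
    one) is asymptotically chi-square on rank(ΔV) degrees of freedom.  A
    Moore–Penrose inverse is used (and flagged) when ΔV is not positive
    definite.
    """
    b0 = np.asarray(complete_case_estimates, dtype=float)
    b1 = np.asarray(imputed_estimates, dtype=float)
    if b0.shape != b1.shape:
        raise ValueError("estimate vectors have mismatched dimensions")
    V0 = np.atleast_2d(np.asarray(complete_case_cov, dtype=float))
    V1 = np.atleast_2d(np.asarray(imputed_cov, dtype=float))
    d = b0 - b1
    dV = V0 - V1
    dV = (dV + dV.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(dV)
    tol = 1e-10 * max(float(np.abs(eigvals).max()), 1.0)
    pd_ok = bool(eigvals.min() > tol)
    if pd_ok:
        stat = float(d @ np.linalg.solve(dV, d))
        df = d.size
    else:
        # generalized inverse restricted to the positive-eigenvalue
        # subspace: directions where the complete-case estimator is not
        # less precise carry no evidence about attrition
        keep = eigvals > tol
        if not keep.any():
            return AttritionCheck(0.0, 1.0, 1, generalized_inverse=True)
        proj = eigvecs[:, keep].T @ d
        stat = float((proj ** 2 / eigvals[keep]).sum())
        df = int(keep.sum())
    stat = max(stat, 0.0)
    df = max(df, 1)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return AttritionCheck(stat, p, df, generalized_inverse=not pd_ok)
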