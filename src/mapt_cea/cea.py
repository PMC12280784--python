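"""Cost-effectiveness core: ICERs, CE-plane bootstrap, ellipses, CEACs.

The incremental cost-effectiveness ratio ICER = ΔC/ΔE is the extra cost
per composite Z-score point gained versus placebo (or per percentage point
of participants without cognitive aggravation, in the binary variant).
Uncertainty is propagated by nonparametric bootstrap of participants,
stratified by arm: each replicate yields a (ΔC, ΔE) pair on the
cost-effectiveness plane, summarised by a 95% confidence ellipse and by
the cost-effectiveness acceptability curve CEAC(λ) = P(λ·ΔE − ΔC > 0)
over a willingness-to-pay grid.  Decision uncertainty is always evaluated
on the net-benefit scale, which stays well defined when replicates fall in
quadrants where the raw ratio does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_trial import ARMS

DEFAULT_WTP = 50_000.0
DEFAULT_WTP_GRID = np.arange(0.0, 150_500.0, 500.0)


@dataclass(frozen=True)
class ICER:
    """Point ICER with cost-effectiveness-plane quadrant semantics."""

    ratio: float
    quadrant: str            # NE, NW(dominant), SE(dominated), SW, undefined
    delta_c: float
    delta_e: float
    caution: bool = False    # SW ratio reported with caution
    defined: bool = True


def icer(delta_c: float, delta_e: float) -> ICER:
    """ICER = ΔC/ΔE with its quadrant.

    ΔC>0, ΔE>0 → NE (ratio is cost per unit gained); ΔC<0, ΔE>0 →
    the intervention dominates (cheaper and more effective); ΔC>0, ΔE<0 →
    dominated; ΔC<0, ΔE<0 → SW, ratio reported with a caution flag;
    ΔE = 0 → the ratio is undefined and flagged, never an exception.
    """
    if delta_e == 0:
        return ICER(float("nan"), "undefined", delta_c, delta_e,
                    defined=False)
    ratio = delta_c / delta_e
    if delta_e > 0:
        quadrant = "NE" if delta_c >= 0 else "dominant"
    else:
        quadrant = "dominated" if delta_c >= 0 else "SW"
    return ICER(ratio, quadrant, delta_c, delta_e,
                caution=(quadrant == "SW"))


@dataclass
class CEReplicates:
    """Bootstrap draws of (ΔC, ΔE) per intervention arm versus placebo."""

    replicates: pd.DataFrame     # arm, b, delta_c, delta_e
    effect_unit: str             # "z" or "binary"
    seed: int
    redrawn: int = 0

    def for_arm(self, arm: str) -> pd.DataFrame:
        return self.replicates[self.replicates["arm"] == arm]

    def to_csv(self, path) -> None:
        self.replicates.to_csv(path, index=False)


def _arm_estimates(frame: pd.DataFrame, arms) -> dict[str, tuple[float, float]]:
    out = {}
    for arm in arms:
        sub = frame[frame["arm"] == arm]
        out[arm] = (float(sub["cost"].mean()),
                    float(sub["effect"].mean()))
    return out


def bootstrap_ce(frames: pd.DataFrame | list[pd.DataFrame],
                 B: int = 1000, seed: int = 0,
                 effect_unit: str = "z",
                 intervention_costs: dict[str, float] | None = None
                 ) -> CEReplicates:
    """Stratified-by-arm nonparametric bootstrap of (ΔC, ΔE).

    ``frames`` is an analysis frame with columns ``arm``, ``cost`` (3-year
    total without intervention, € — the deterministic intervention cost
    difference from ``intervention_costs`` is added to ΔC after averaging)
    and ``effect``; pass a list of frames (one per imputed dataset) to
    propagate imputation uncertainty — replicate ``b`` resamples frame
    ``b mod m``.  Each replicate draws participants with replacement
    within each arm and recomputes arm-mean differences versus placebo
    (fast mode).  Fully reproducible from ``seed``.
    """
    if isinstance(frames, pd.DataFrame):
        frames = [frames]
    rng = np.random.default_rng(seed)
    arms = [a for a in ARMS if a != "placebo"]
    icosts = intervention_costs or {a: 0.0 for a in ARMS}

    # pre-split indices per frame and arm for speed
    splits = []
    for fr in frames:
        fr = fr.reset_index(drop=True)
        d = {}
        for arm in ARMS:
            sub = fr[fr["arm"] == arm]
            cost = sub["cost"].to_numpy(float)
            eff = sub["effect"].to_numpy(float)
            if len(sub) == 0:
                raise ValueError(f"arm {arm!r} has no participants")
            d[arm] = (cost, eff)
        splits.append(d)

    rows = []
    for b in range(B):
        d = splits[b % len(splits)]
        means = {}
        for arm in ARMS:
            cost, eff = d[arm]
            idx = rng.integers(0, len(cost), len(cost))
            c = cost[idx]
            e = eff[idx]
            means[arm] = (np.nanmean(c), np.nanmean(e))
        for arm in arms:
            dc = (means[arm][0] - means["placebo"][0]
                  + icosts.get(arm, 0.0) - icosts.get("placebo", 0.0))
            de = means[arm][1] - means["placebo"][1]
            rows.append((arm, b + 1, dc, de))
    reps = pd.DataFrame(rows, columns=["arm", "b", "delta_c", "delta_e"])
    if not np.isfinite(reps[["delta_c", "delta_e"]].to_numpy()).all():
        raise ValueError("non-finite bootstrap replicates (all-missing arm?)")
    return CEReplicates(replicates=reps, effect_unit=effect_unit, seed=seed)


@dataclass
class Ellipse:
    """CE-plane confidence ellipse {x : (x−μ)ᵀΣ⁻¹(x−μ) ≤ χ²₂(level)} in
    (ΔE, ΔC) coordinates."""

    center: np.ndarray           # (mean ΔE, mean ΔC)
    cov: np.ndarray              # 2×2 replicate covariance
    level: float
    radius2: float               # χ²₂ quantile
    polygon: np.ndarray          # points on the boundary, (n, 2)
    degenerate: bool = False

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of (n, 2) points inside the ellipse."""
        if self.degenerate:
            return np.all(np.isclose(points, self.center), axis=1)
        d = points - self.center
        m = np.einsum("ij,jk,ik->i", d, np.linalg.inv(self.cov), d)
        return m <= self.radius2


def confidence_ellipse(reps: CEReplicates | pd.DataFrame, arm: str | None = None,
                       level: float = 0.95, n_points: int = 200) -> Ellipse:
    """95% confidence ellipse of the bootstrap (ΔE, ΔC) cloud.

    Centered at the replicate means with the replicate covariance; the
    boundary is the χ²₂(level) Mahalanobis contour.  A singular covariance
    (e.g. all replicates identical) yields a degenerate flagged ellipse.
    """
    df = reps.for_arm(arm) if isinstance(reps, CEReplicates) else reps
    if len(df) < 10:
        raise ValueError("need at least 10 replicates for an ellipse")
    pts = df[["delta_e", "delta_c"]].to_numpy(float)
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    radius2 = float(stats.chi2.ppf(level, df=2))
    det = float(np.linalg.det(cov))
    if not np.isfinite(det) or det <= 1e-300:
        return Ellipse(center=center, cov=cov, level=level, radius2=radius2,
                       polygon=np.repeat(center[None, :], n_points, axis=0),
                       degenerate=True)
    vals, vecs = np.linalg.eigh(cov)
    theta = np.linspace(0.0, 2 * np.pi, n_points)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    boundary = center + (circle * np.sqrt(vals * radius2)) @ vecs.T
    return Ellipse(center=center, cov=cov, level=level, radius2=radius2,
                   polygon=boundary)


@dataclass
class CEAC:
    """Cost-effectiveness acceptability curve over a WTP grid."""

    curve: pd.DataFrame          # wtp, probability
    at_reference: float          # probability at the €50,000 threshold
    reference_wtp: float = DEFAULT_WTP

    def probability_at(self, wtp: float) -> float:
        i = (self.curve["wtp"] - wtp).abs().idxmin()
        return float(self.curve.loc[i, "probability"])


def ceac(reps: CEReplicates | pd.DataFrame, arm: str | None = None,
         wtp_grid: np.ndarray | None = None,
         reference_wtp: float = DEFAULT_WTP) -> CEAC:
    """CEAC(λ) = fraction of replicates with positive net benefit λ·ΔE − ΔC.

    At λ = 0 this is P(ΔC < 0); as λ → ∞ it tends to P(ΔE > 0).
    """
    grid = np.asarray(DEFAULT_WTP_GRID if wtp_grid is None else wtp_grid,
                      dtype=float)
    if grid.size == 0 or (grid < 0).any():
        raise ValueError("WTP grid must be nonempty and nonnegative")
    df = reps.for_arm(arm) if isinstance(reps, CEReplicates) else reps
    dc = df["delta_c"].to_numpy(float)
    de = df["delta_e"].to_numpy(float)
    prob = ((grid[:, None] * de[None, :] - dc[None, :]) > 0).mean(axis=1)
    curve = pd.DataFrame({"wtp": grid, "probability": prob})
    at_ref = float(((reference_wtp * de - dc) > 0).mean())
    return CEAC(curve=curve, at_reference=at_ref, reference_wtp=reference_wtp)


def binary_effectiveness(z_changes, cutoff: float = -0.3,
                         strict: bool = True) -> float:
    """Percentage of participants without cognitive aggravation.

    A 0.3-point composite-Z decrease is the minimum clinically significant
    decline (it predicts dementia), so a participant counts as "no
    aggravation" iff change > cutoff (with ``strict=True`` the boundary
    value itself counts as aggravation; set ``strict=False`` to include it).
    Missing changes are ignored; an all-missing input is an error.
    """
    x = np.asarray(pd.Series(z_changes).dropna(), dtype=float)
    if x.size == 0:
        raise ValueError("no non-missing change scores")
    ok = (x > cutoff) if strict else (x >= cutoff)
    return float(100.0 * ok.mean())
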