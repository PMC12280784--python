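"""Payer-perspective valuation of resource use and intervention pricing.

Hospital-type payment systems (DRG rates, per-diem tariffs, procedure
nomenclatures) are abstracted into a configurable :class:`TariffTable`
mapping each resource subcategory to one of four valuation rules:

- ``fixed_tariff`` — quantity × unit cost (consultations, procedures);
- ``per_diem`` — length of stay in days × daily rate (hospital stays);
- ``ddd_drug`` — reimbursement price per unit × defined daily dose (DDD)
  × treatment duration in days (dispensed medications);
- ``gamma_sampled`` — per-event cost drawn from a gamma distribution whose
  shape and scale are moment-matched to an observed mean and variance
  (components for which only frequencies are recorded, e.g. paramedical
  procedures and transportation valued from claims-database averages).

Interventions are priced directly: the multidomain intervention (MI) at a
facilitator wage rate × session length × number of sessions priced, and
omega-3 supplementation (PFA) at a retail price per capsule × capsules per
year × horizon.  All monetary values are 2018 euros.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_trial import ARMS, PERIODS, TrialConfig, TrialDataset

VALUATION_RULES = ("fixed_tariff", "per_diem", "ddd_drug", "gamma_sampled")


class TariffError(KeyError):
    """Raised when an event's subcategory has no tariff rule."""


@dataclass(frozen=True)
class TariffRule:
    """Valuation rule for one resource subcategory."""

    rule: str
    unit_cost: float = 0.0        # fixed_tariff: € per unit quantity
    per_diem_rate: float = 0.0    # per_diem: € per day
    price_per_unit: float = 0.0   # ddd_drug: € per dose unit
    ddd: float = 0.0              # ddd_drug: dose units per day
    gamma_shape: float = 0.0      # gamma_sampled
    gamma_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.rule not in VALUATION_RULES:
            raise ValueError(f"unknown valuation rule {self.rule!r}")
        for name in ("unit_cost", "per_diem_rate", "price_per_unit", "ddd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rule == "gamma_sampled" and (self.gamma_shape <= 0
                                             or self.gamma_scale <= 0):
            raise ValueError("gamma shape and scale must be strictly positive")

    @staticmethod
    def gamma_from_moments(mean: float, var: float) -> "TariffRule":
        """Moment-matched gamma rule: shape = m²/v, scale = v/m."""
        if mean <= 0 or var <= 0:
            raise ValueError("mean and variance must be strictly positive")
        return TariffRule("gamma_sampled", gamma_shape=mean ** 2 / var,
                          gamma_scale=var / mean)


@dataclass(frozen=True)
class TariffTable:
    """Unit costs per resource subcategory plus intervention pricing.

    Intervention defaults: MI sessions at a €40/h facilitator wage for
    2.30-hour sessions, 10 sessions priced (a group-shared schedule that
    reproduces a €920 per-participant MI cost; the full individual schedule
    of ~46 sessions is available by overriding ``mi_sessions_priced``), and
    PFA at €0.50 per capsule × 365.5 capsules/year × 3 years = €548.25.
    """

    rules: dict[str, TariffRule]
    mi_hourly_wage: float = 40.0
    mi_session_hours: float = 2.30
    mi_sessions_priced: float = 10.0
    pfa_price_per_capsule: float = 0.50
    pfa_capsules_per_year: float = 365.5
    horizon_years: float = 3.0

    def rule_for(self, subcategory: str) -> TariffRule:
        try:
            return self.rules[subcategory]
        except KeyError:
            raise TariffError(
                f"no tariff rule for subcategory {subcategory!r}; "
                f"known: {sorted(self.rules)}") from None

    @classmethod
    def from_config(cls, config: TrialConfig | None = None, **kwargs
                    ) -> "TariffTable":
        """Build the tariff table matching a synthetic trial's component
        specification (the default table for pipeline runs)."""
        config = config or TrialConfig()
        rules: dict[str, TariffRule] = {}
        for comp in config.cost_components:
            if comp.rule == "fixed_tariff":
                rules[comp.subcategory] = TariffRule(
                    "fixed_tariff", unit_cost=comp.unit_cost)
            elif comp.rule == "per_diem":
                rules[comp.subcategory] = TariffRule(
                    "per_diem", per_diem_rate=comp.per_diem_rate)
            elif comp.rule == "ddd_drug":
                rules[comp.subcategory] = TariffRule(
                    "ddd_drug", price_per_unit=comp.price_per_unit,
                    ddd=comp.ddd)
            else:
                rules[comp.subcategory] = TariffRule.gamma_from_moments(
                    comp.gamma_mean, comp.gamma_var)
        return cls(rules=rules, **kwargs)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["rules"] = {k: dataclasses.asdict(v) for k, v in self.rules.items()}
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TariffTable":
        d = json.loads(Path(path).read_text())
        d["rules"] = {k: TariffRule(**v) for k, v in d["rules"].items()}
        return cls(**d)


@dataclass
class CostPanel:
    """Per-participant, per-period, per-component payer costs.

    ``costs`` is tidy (participant_id, period_index, component, cost);
    ``totals`` has one row per participant with the 3-year cumulative total
    without intervention, the intervention cost, and their exact sum.
    """

    costs: pd.DataFrame
    totals: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.costs.to_csv(path, index=False)


def intervention_cost(arm: str, tariffs: TariffTable) -> float:
    """Price the intervention received by one arm over the trial horizon.

    PFA component: price per capsule × capsules/year × horizon years.
    MI component: hourly wage × session hours × sessions priced.
    The combined arm pays both; placebo pays nothing.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm label {arm!r}; expected one of {ARMS}")
    pfa = (tariffs.pfa_price_per_capsule * tariffs.pfa_capsules_per_year
           * tariffs.horizon_years)
    mi = (tariffs.mi_hourly_wage * tariffs.mi_session_hours
          * tariffs.mi_sessions_priced)
    return {"PFA+MI": pfa + mi, "PFA": pfa, "MI": mi, "placebo": 0.0}[arm]


def _event_costs(events: pd.DataFrame, tariffs: TariffTable,
                 rng: np.random.Generator) -> np.ndarray:
    qty = events["quantity"].to_numpy(float)
    if (qty < 0).any():
        bad = events.loc[qty < 0, "participant_id"].iloc[0]
        raise ValueError(f"negative event quantity (participant {bad})")
    cost = np.zeros(len(events))
    for sub, idx in events.groupby("subcategory", sort=True).groups.items():
        rule = tariffs.rule_for(sub)
        sel = events.loc[idx]
        if rule.rule == "fixed_tariff":
            c = sel["quantity"].to_numpy(float) * rule.unit_cost
        elif rule.rule == "per_diem":
            days = sel["length_of_stay_days"].to_numpy(float)
            if np.isnan(days).any():
                raise ValueError(f"per_diem events for {sub!r} need "
                                 "length_of_stay_days")
            c = days * rule.per_diem_rate
        elif rule.rule == "ddd_drug":
            dur = sel["duration_days"].to_numpy(float)
            if np.isnan(dur).any():
                raise ValueError(f"ddd_drug events for {sub!r} need "
                                 "duration_days")
            c = rule.price_per_unit * rule.ddd * dur
        else:  # gamma_sampled: sum of `quantity` iid draws
            k = sel["quantity"].to_numpy(float)
            c = np.where(k > 0,
                         rng.gamma(rule.gamma_shape * np.maximum(k, 1e-12),
                                   rule.gamma_scale),
                         0.0)
        cost[events.index.get_indexer(idx)] = c
    return cost


def value_events(events: pd.DataFrame, tariffs: TariffTable, seed: int = 0,
                 participants: pd.DataFrame | None = None) -> CostPanel:
    """Value every resource-use event and assemble the cost panel.

    ``participants`` (with ``participant_id`` and ``arm``) fixes the set of
    participants — those without any event get zero totals — and supplies
    the arm needed to price the intervention.  Gamma-valued subcategories
    are sampled reproducibly from ``seed``.
    """
    rng = np.random.default_rng(seed)
    if len(events):
        ev = events.reset_index(drop=True)
        ev = ev.assign(cost=_event_costs(ev, tariffs, rng))
        costs = (ev.groupby(["participant_id", "period_index", "category"],
                            as_index=False)["cost"].sum()
                 .rename(columns={"category": "component"}))
        per_participant = costs.groupby("participant_id")["cost"].sum()
    else:
        costs = pd.DataFrame(columns=["participant_id", "period_index",
                                      "component", "cost"])
        per_participant = pd.Series(dtype=float, name="cost")

    if participants is not None:
        ids = participants["participant_id"]
        without = per_participant.reindex(ids, fill_value=0.0).to_numpy()
        interv = participants["arm"].map(
            lambda a: intervention_cost(a, tariffs)).to_numpy(float)
        totals = pd.DataFrame({
            "participant_id": ids.to_numpy(),
            "arm": participants["arm"].to_numpy(),
            "cumulative_3y_without_intervention": without,
            "intervention_cost": interv,
        })
    else:
        totals = pd.DataFrame({
            "participant_id": per_participant.index.to_numpy(),
            "arm": pd.NA,
            "cumulative_3y_without_intervention": per_participant.to_numpy(),
            "intervention_cost": 0.0,
        })
    totals["cumulative_3y_with_intervention"] = (
        totals["cumulative_3y_without_intervention"]
        + totals["intervention_cost"])
    return CostPanel(costs=costs, totals=totals)


def cumulative_costs(panel: CostPanel, include_intervention: bool = True
                     ) -> pd.Series:
    """Per-participant 3-year cumulative totals (€), summing all components
    over the six half-year windows, plus the intervention cost iff requested."""
    col = ("cumulative_3y_with_intervention" if include_intervention
           else "cumulative_3y_without_intervention")
    return panel.totals.set_index("participant_id")[col]


def cost_panel_for(dataset: TrialDataset, tariffs: TariffTable | None = None,
                   seed: int | None = None) -> CostPanel:
    """Convenience: value a trial dataset's events with its matched tariffs.

    Participants flagged ``econ_missing`` get missing (NaN) cumulative
    totals, mirroring incomplete economic follow-up.
    """
    tariffs = tariffs or TariffTable.from_config(dataset.config)
    if seed is None:
        seed = dataset.config.random_seed + 7_000_000
    panel = value_events(dataset.events, tariffs, seed=seed,
                         participants=dataset.participants)
    if "econ_missing" in dataset.participants:
        miss = dataset.participants.set_index("participant_id")["econ_missing"]
        mask = panel.totals["participant_id"].map(miss).fillna(False)
        panel.totals.loc[mask.to_numpy(bool),
                         ["cumulative_3y_without_intervention",
                          "cumulative_3y_with_intervention"]] = np.nan
    return panel


def observed_periods(events: pd.DataFrame) -> pd.DataFrame:
    """Participant × period indicator of any recorded resource use."""
    return (events.assign(seen=1)
            .pivot_table(index="participant_id", columns="period_index",
                         values="seen", aggfunc="max", fill_value=0)
            .reindex(columns=list(PERIODS), fill_value=0))
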