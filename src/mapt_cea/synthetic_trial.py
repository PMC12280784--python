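"""Synthetic four-arm prevention-trial generator.

Emulates a multidomain Alzheimer prevention trial: four parallel arms
(omega-3 supplementation ``PFA``, multidomain intervention ``MI``, their
combination ``PFA+MI``, and placebo), community-dwelling participants aged
70+ recruited across memory centers, longitudinal cognitive testing over
three years, and event-level healthcare resource use collected in six-month
windows.  Every downstream stage of the cost-effectiveness pipeline is
testable against the known ground-truth parameters of this generator.

The cognitive outcome is built so that the expected 36-month composite
Z-score difference of each intervention arm versus placebo equals the
configured ``true_z_effects``; healthcare costs are right-skewed with
per-participant intensity depending on age and comorbidity count, matching
the structure of a payer-perspective resource-use file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

ARMS = ("PFA+MI", "PFA", "MI", "placebo")
VISIT_MONTHS = (0, 6, 12, 24, 36)
PERIODS = (1, 2, 3, 4, 5, 6)
COGNITIVE_TESTS = ("fcsrt_recall", "mmse_orientation", "dsst", "category_fluency")
FRAILTY_LEVELS = ("robust", "pre-frail", "frail")
EDUCATION_LEVELS = ("primary", "secondary", "high_school", "university")

#: baseline scale (mean, SD) of each raw cognitive test in the cohort
TEST_SCALES = {
    "fcsrt_recall": (75.0, 9.0),
    "mmse_orientation": (9.6, 0.7),
    "dsst": (40.0, 10.0),
    "category_fluency": (19.0, 5.0),
}

#: prevalence of each medical-history category at baseline (pooled arms)
CONDITION_PREVALENCES = {
    "skin": 0.080,
    "gastrointestinal": 0.386,
    "genitourinary": 0.277,
    "respiratory": 0.037,
    "eye": 0.155,
    "ent": 0.246,
    "blood_immune": 0.064,
    "nervous_system": 0.316,
    "musculoskeletal": 0.726,
    "endocrine_metabolic": 0.614,
    "infectious": 0.177,
    "mental_behavioral": 0.268,
    "cancer": 0.290,
    "cardiovascular": 0.749,
    "benign_tumor": 0.138,
}


class ConfigError(ValueError):
    """Raised when a trial configuration field is invalid."""


@dataclass(frozen=True)
class CostComponentSpec:
    """One resource-use component of the synthetic cost model.

    ``events_per_period`` is the expected number of events per participant
    per six-month window (placebo arm, average covariates).  The valuation
    ``rule`` mirrors the tariff rules used downstream:

    - ``fixed_tariff``: each event costs ``unit_cost`` euros per unit quantity;
    - ``per_diem``: each event carries a gamma-distributed length of stay
      (mean ``los_mean_days``, coefficient of variation ``los_cv``) priced at
      ``per_diem_rate`` €/day;
    - ``ddd_drug``: each dispensation covers ``duration_days`` at the defined
      daily dose ``ddd`` of a drug priced ``price_per_unit`` €/unit;
    - ``gamma_sampled``: events are valued by gamma draws with the given
      per-event mean and variance (moment-matched shape/scale downstream).
    """

    category: str
    subcategory: str
    events_per_period: float
    rule: str
    unit_cost: float = 0.0
    per_diem_rate: float = 0.0
    los_mean_days: float = 0.0
    los_cv: float = 0.7
    price_per_unit: float = 0.0
    ddd: float = 0.0
    duration_days: float = 0.0
    gamma_mean: float = 0.0
    gamma_var: float = 0.0


def default_cost_components() -> tuple[CostComponentSpec, ...]:
    """Component mix calibrated so the placebo-arm 3-year mean total is ≈ €7,100.

    Per-component 3-year means: inpatient ≈ €3,829, consultations ≈ €495,
    paramedical ≈ €393, medical procedures ≈ €228, transportation ≈ €15,
    medications ≈ €2,137 — split uniformly across the six half-year windows.
    """
    return (
        CostComponentSpec("inpatient", "acute_stay", 0.95 / 6, "per_diem",
                          per_diem_rate=806.0, los_mean_days=5.0, los_cv=0.7),
        CostComponentSpec("consultation", "general_practitioner", 15.05 / 6,
                          "fixed_tariff", unit_cost=16.48),
        CostComponentSpec("consultation", "specialist", 12.90 / 6,
                          "fixed_tariff", unit_cost=19.15),
        CostComponentSpec("paramedical", "paramedical_procedure", 21.80 / 6,
                          "gamma_sampled", gamma_mean=18.03, gamma_var=549.4),
        CostComponentSpec("medical_procedure", "medical_procedure", 22.06 / 6,
                          "fixed_tariff", unit_cost=10.34),
        CostComponentSpec("transportation", "trip", 0.49 / 6,
                          "gamma_sampled", gamma_mean=30.6, gamma_var=936.4),
        CostComponentSpec("medication", "dispensation", 31.78 / 6, "ddd_drug",
                          price_per_unit=0.3736, ddd=2.0, duration_days=90.0),
    )


@dataclass(frozen=True)
class TrialConfig:
    """Ground-truth parameters of the synthetic trial.

    Defaults reproduce the scale of the source trial design: ~380
    participants per arm in 13 centers, 36-month composite-Z arm effects of
    0.093 / 0.011 / 0.079 Z-points versus placebo for the combined, PFA and
    MI arms, 12–15% missing economic data per arm, and right-skewed cost
    components summing to ≈ €7,100 per placebo participant over three years.
    """

    n_per_arm: int = 380
    arm_labels: tuple[str, ...] = ARMS
    true_z_effects: dict[str, float] = field(
        default_factory=lambda: {"PFA+MI": 0.093, "PFA": 0.011, "MI": 0.079,
                                 "placebo": 0.0})
    n_centers: int = 13
    random_seed: int = 0
    missing_econ_rate: float = 0.135
    cognitive_dropout_rate: float = 0.15

    # baseline covariate distributions
    age_mean: float = 75.3
    age_sd: float = 4.4
    age_min: float = 70.0
    prop_male: float = 0.359
    frailty_probs: tuple[float, float, float] = (0.564, 0.408, 0.028)
    education_probs: tuple[float, float, float, float] = (0.225, 0.340, 0.145, 0.290)

    # cognitive generative model (composite-Z scale)
    visit_months: tuple[int, ...] = VISIT_MONTHS
    placebo_visit_effects: tuple[float, ...] = (0.0, -0.03, -0.06, -0.12, -0.18)
    center_intercept_sd: float = 0.05
    participant_intercept_sd: float = 0.65
    occasion_sd: float = 0.25
    test_noise_sd: float = 0.716

    # cost generative model
    cost_components: tuple[CostComponentSpec, ...] = field(
        default_factory=default_cost_components)
    arm_cost_multipliers: dict[str, float] = field(
        default_factory=lambda: {"PFA+MI": 1.084, "PFA": 1.119, "MI": 1.104,
                                 "placebo": 1.0})
    cost_log_age_effect: float = 0.03      # per year of age, on event intensity
    cost_log_condition_effect: float = 0.16  # per medical condition
    cost_frailty_sd: float = 0.8           # lognormal participant heterogeneity

    def validate(self) -> None:
        if len(self.arm_labels) != 4:
            raise ConfigError("arm_labels: exactly 4 arms are required")
        if self.n_per_arm < 2:
            raise ConfigError("n_per_arm: must be at least 2")
        if set(self.true_z_effects) != set(self.arm_labels):
            raise ConfigError("true_z_effects: must key every arm label")
        if self.true_z_effects.get("placebo", 0.0) != 0.0:
            raise ConfigError("true_z_effects: placebo effect must be 0")
        for name in ("missing_econ_rate", "cognitive_dropout_rate", "prop_male"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: proportion must lie in [0, 1]")
        for probs, name in ((self.frailty_probs, "frailty_probs"),
                            (self.education_probs, "education_probs")):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-6:
                raise ConfigError(f"{name}: must be a probability vector")
        if self.n_centers < 1:
            raise ConfigError("n_centers: must be positive")
        if len(self.placebo_visit_effects) != len(self.visit_months):
            raise ConfigError("placebo_visit_effects: one value per visit")
        for comp in self.cost_components:
            if comp.rule not in ("fixed_tariff", "per_diem", "ddd_drug",
                                 "gamma_sampled"):
                raise ConfigError(f"cost_components: unknown rule {comp.rule!r}")
            if comp.events_per_period < 0:
                raise ConfigError("cost_components: event rate must be >= 0")
            if comp.rule == "gamma_sampled" and (comp.gamma_mean <= 0
                                                 or comp.gamma_var <= 0):
                raise ConfigError("cost_components: gamma mean and variance "
                                  "must be strictly positive")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["cost_components"] = [dataclasses.asdict(c) for c in self.cost_components]
        Path(path).write_text(json.dumps(d, indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrialConfig":
        d = json.loads(Path(path).read_text())
        d["cost_components"] = tuple(
            CostComponentSpec(**c) for c in d["cost_components"])
        for k in ("arm_labels", "frailty_probs", "education_probs",
                  "visit_months", "placebo_visit_effects"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class TrialDataset:
    """In-memory trial data: one row per participant, long-format cognitive
    panel (one row per participant × visit), and event-level resource use."""

    participants: pd.DataFrame
    cognition: pd.DataFrame
    events: pd.DataFrame
    config: TrialConfig

    @property
    def arms(self) -> tuple[str, ...]:
        return self.config.arm_labels

    def to_csv(self, directory: str | Path) -> None:
        """Write participants.csv, cognition.csv, resource_events.csv and
        config.json into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(directory / "participants.csv", index=False)
        self.cognition.to_csv(directory / "cognition.csv", index=False)
        self.events.to_csv(directory / "resource_events.csv", index=False)
        self.config.to_json(directory / "config.json")

    @classmethod
    def from_csv(cls, directory: str | Path) -> "TrialDataset":
        directory = Path(directory)
        return cls(
            participants=pd.read_csv(directory / "participants.csv"),
            cognition=pd.read_csv(directory / "cognition.csv"),
            events=pd.read_csv(directory / "resource_events.csv"),
            config=TrialConfig.from_json(directory / "config.json"),
        )


def _generate_participants(config: TrialConfig, rng: np.random.Generator
                           ) -> pd.DataFrame:
    n = config.n_per_arm * 4
    arm = np.repeat(list(config.arm_labels), config.n_per_arm)
    # truncated-normal ages, eligibility at age_min
    age = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.normal(config.age_mean, config.age_sd, todo.size)
        ok = draw >= config.age_min
        age[todo[ok]] = draw[ok]
        todo = todo[~ok]
    conditions = rng.random((n, len(CONDITION_PREVALENCES))) < np.array(
        list(CONDITION_PREVALENCES.values()))
    df = pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "arm": arm,
        "center_id": rng.integers(1, config.n_centers + 1, n),
        "age_years": np.round(age, 1),
        "male": (rng.random(n) < config.prop_male).astype(int),
        "frailty": rng.choice(FRAILTY_LEVELS, n, p=config.frailty_probs),
        "education": rng.choice(EDUCATION_LEVELS, n, p=config.education_probs),
        "n_medical_conditions": conditions.sum(axis=1),
    })
    return df


def _generate_cognition(config: TrialConfig, participants: pd.DataFrame,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Latent composite trajectory + per-test measurement noise.

    The latent scale is normalised so the baseline cohort SD of each raw
    test is its nominal SD: downstream standardisation then recovers the
    latent composite, and the 36-month arm-versus-placebo contrast of the
    composite has expectation ``true_z_effects``.
    """
    n = len(participants)
    months = np.array(config.visit_months)
    ramp = months / months[-1]
    center_u = rng.normal(0.0, config.center_intercept_sd, config.n_centers)
    subj_b = rng.normal(0.0, config.participant_intercept_sd, n)
    arm_eff = participants["arm"].map(config.true_z_effects).to_numpy(float)

    # n × visits latent trajectory
    traj = (center_u[participants["center_id"].to_numpy() - 1][:, None]
            + subj_b[:, None]
            + np.array(config.placebo_visit_effects)[None, :]
            + arm_eff[:, None] * ramp[None, :]
            + rng.normal(0.0, config.occasion_sd, (n, months.size)))

    rows = {
        "participant_id": np.repeat(participants["participant_id"].to_numpy(),
                                    months.size),
        "month": np.tile(months, n),
    }
    for test in COGNITIVE_TESTS:
        mu, sigma = TEST_SCALES[test]
        noise = rng.normal(0.0, config.test_noise_sd, (n, months.size))
        rows[test] = (mu + sigma * (traj + noise)).ravel()
    return pd.DataFrame(rows)


def _generate_events(config: TrialConfig, participants: pd.DataFrame,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Poisson event counts per component × period with per-participant
    intensity multipliers (age, comorbidity count, lognormal frailty)."""
    age_c = participants["age_years"].to_numpy() - config.age_mean
    cond_c = (participants["n_medical_conditions"].to_numpy()
              - participants["n_medical_conditions"].mean())
    log_mult = (config.cost_log_age_effect * age_c
                + config.cost_log_condition_effect * cond_c
                + rng.normal(0.0, config.cost_frailty_sd, len(participants)))
    mult = np.exp(log_mult)
    mult /= mult.mean()
    arm_mult = participants["arm"].map(config.arm_cost_multipliers).to_numpy(float)
    pid = participants["participant_id"].to_numpy()

    frames = []
    for comp in config.cost_components:
        lam = comp.events_per_period * mult * arm_mult
        for period in PERIODS:
            counts = rng.poisson(lam)
            keep = counts > 0
            if not keep.any():
                continue
            # one record per event
            idx = np.repeat(np.nonzero(keep)[0], counts[keep])
            ev = pd.DataFrame({
                "participant_id": pid[idx],
                "period_index": period,
                "category": comp.category,
                "subcategory": comp.subcategory,
                "quantity": 1.0,
            })
            if comp.rule == "per_diem":
                shape = 1.0 / comp.los_cv ** 2
                scale = comp.los_mean_days / shape
                ev["length_of_stay_days"] = np.round(
                    rng.gamma(shape, scale, len(ev)), 1)
            else:
                ev["length_of_stay_days"] = np.nan
            if comp.rule == "ddd_drug":
                ev["drug_code"] = comp.subcategory
                ev["duration_days"] = comp.duration_days
            else:
                ev["drug_code"] = ""
                ev["duration_days"] = np.nan
            frames.append(ev)
    events = pd.concat(frames, ignore_index=True)
    return events.sort_values(["participant_id", "period_index", "category",
                               "subcategory"], kind="stable",
                              ignore_index=True)


def generate_trial(config: TrialConfig | None = None) -> TrialDataset:
    """Generate a complete (no missing data) synthetic four-arm trial.

    Fully reproducible from ``config.random_seed``: the same configuration
    always yields byte-identical frames.
    """
    config = config or TrialConfig()
    config.validate()
    rng = np.random.default_rng(config.random_seed)
    participants = _generate_participants(config, rng)
    cognition = _generate_cognition(config, participants, rng)
    events = _generate_events(config, participants, rng)
    participants["econ_missing"] = False
    return TrialDataset(participants, cognition, events, config)


def _tercile(values: np.ndarray) -> np.ndarray:
    """0/1/2 tercile codes on the observed marginal, ties to the lower tercile."""
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    return (values > q1).astype(int) + (values > q2).astype(int)


def _mar_probabilities(participants: pd.DataFrame, rate: float,
                       slope_age: float = 0.5, slope_frail: float = 0.6
                       ) -> np.ndarray:
    """Missingness probabilities driven by age tercile and frailty, with the
    intercept solved per arm so the expected missing fraction equals ``rate``."""
    age_ter = _tercile(participants["age_years"].to_numpy())
    frail = participants["frailty"].map(
        {level: i for i, level in enumerate(FRAILTY_LEVELS)}).to_numpy()
    lin = slope_age * age_ter + slope_frail * frail
    probs = np.empty(len(participants))
    for arm in participants["arm"].unique():
        mask = (participants["arm"] == arm).to_numpy()
        if rate <= 0.0:
            probs[mask] = 0.0
            continue
        if rate >= 1.0:
            probs[mask] = 1.0
            continue
        f = lambda c: expit(c + lin[mask]).mean() - rate  # noqa: E731
        c0 = brentq(f, -30.0, 30.0)
        probs[mask] = expit(c0 + lin[mask])
    return probs


def apply_missingness(dataset: TrialDataset,
                      config: TrialConfig | None = None) -> TrialDataset:
    """Impose missing-at-random economic data and cognitive dropout.

    A fraction ``missing_econ_rate`` of each arm (in expectation) has its
    3-year cumulative economic data flagged missing; the probability depends
    only on observed covariates (age tercile, frailty), so the mechanism is
    MAR by construction.  Cognitive dropout removes post-baseline visits
    from a uniformly chosen visit onward with the same covariate-driven
    probability structure.  The input dataset is not modified.
    """
    config = config or dataset.config
    if not 0.0 <= config.missing_econ_rate <= 1.0:
        raise ConfigError("missing_econ_rate: must lie in [0, 1]")
    if not 0.0 <= config.cognitive_dropout_rate <= 1.0:
        raise ConfigError("cognitive_dropout_rate: must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.random_seed, 2 ** 16 + 1]))
    participants = dataset.participants.copy()
    cognition = dataset.cognition.copy()

    econ_p = _mar_probabilities(participants, config.missing_econ_rate)
    participants["econ_missing"] = rng.random(len(participants)) < econ_p

    drop_p = _mar_probabilities(participants, config.cognitive_dropout_rate)
    dropped = rng.random(len(participants)) < drop_p
    post_baseline = [m for m in config.visit_months if m > 0]
    drop_from = rng.choice(post_baseline, len(participants))
    drop_month = np.where(dropped, drop_from, np.inf)
    cutoff = cognition["participant_id"].map(
        pd.Series(drop_month, index=participants["participant_id"])).to_numpy()
    lost = cognition["month"].to_numpy() >= cutoff
    cognition.loc[lost, list(COGNITIVE_TESTS)] = np.nan
    return TrialDataset(participants, cognition, dataset.events, config)
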