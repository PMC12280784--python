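# Methods

This note documents the models behind `mapt_cea`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Study design being emulated

A multicenter, randomized, placebo-controlled superiority trial with four
parallel arms — multidomain intervention plus placebo capsules (MI),
omega-3 polyunsaturated fatty acid supplementation (PFA), their
combination (PFA+MI), and placebo — in community-dwelling adults aged 70
and older recruited at 13 memory centers and followed for three years.
Healthcare resource use is recorded in six half-year windows and valued
from the payer perspective in 2018 euros; the efficacy outcome is the
change from baseline to 36 months in a composite cognitive Z score.

## Synthetic trial generator

The generator (`synthetic_trial`) is first-class, tested code: it defines
the study conditions under which every downstream stage is validated.

**Baseline covariates.** Age is truncated normal (mean 75.3, SD 4.4,
minimum 70 — the eligibility floor); gender is Bernoulli (35.9% male);
frailty is categorical (robust 56.4%, pre-frail 40.8%, frail 2.8%);
education has four levels; the medical-history count is the sum of 15
independent condition indicators with realistic prevalences (range 0–15,
within the 0–16 support used for tercile coding). Participants are
allocated equally to arms and uniformly to centers.

**Cognition.** A latent composite trajectory is simulated per participant:
center random intercept (SD 0.05 — small relative to residual variation,
as center effects in multicenter cognition trials typically are),
participant random intercept (SD 0.65), visit fixed effects (a gentle
placebo decline reaching −0.18 Z by 36 months), an arm effect ramping
linearly to its full value at 36 months, and occasion noise (SD 0.25).
Each of the four raw test scores is the latent trajectory plus independent
test noise (SD 0.716) mapped onto its native scale (e.g. DSST mean 40,
SD 10). The four variance components sum to one at baseline, so
standardising each test to the baseline cohort recovers the latent scale
and the expected 36-month arm-versus-placebo composite contrast equals the
configured `true_z_effects` — defaults 0.093 (PFA+MI), 0.079 (MI), 0.011
(PFA), the reference scale for this design. The implied SE of a 36-month
contrast at 380/arm is ≈0.046, matching a reported CI half-width of
≈0.09.

**Visit grid.** Cognition at 0/6/12/24/36 months, costs in six half-year
windows. Cost collection at six-month intervals is part of the design
being emulated; the cognitive visit spacing follows the usual schedule of
this trial family and is configurable.

**Costs.** Seven resource components (acute inpatient stays, GP and
specialist consultations, paramedical procedures, medical procedures,
transportation, drug dispensations) with Poisson event counts per window
and component-specific valuation rules. Default rates and intensities are
calibrated so the placebo-arm 3-year mean total is ≈€7,100, split as
inpatient ≈€3,829, medications ≈€2,137, consultations ≈€495, paramedical
≈€393, procedures ≈€228, transportation ≈€15 — the reference cost
structure, split uniformly across windows (per-window trends are not
modelled). Event intensity is participant-specific:
log-multiplier = 0.03·(age−75.3) + 0.16·(conditions−mean) + N(0, 0.8²),
normalised to mean one. The age and comorbidity gradients reproduce
total-cost relative risks of ≈1.3 across age terciles and ≈2.2 across
comorbidity terciles; the lognormal term produces the heavy right tail
characteristic of healthcare costs. Arm-level rate multipliers (1.084,
1.119, 1.104 for PFA+MI, PFA, MI) reproduce the observed pattern of
slightly higher non-intervention costs in the active arms. Within-
participant correlation of costs across windows comes entirely from the
shared multiplier; no additional serial correlation is modelled.

**Missingness.** Economic missingness is imposed on the 3-year cumulative
level: the probability is logistic in age tercile and frailty, with the
intercept solved per arm so the expected missing fraction equals
`missing_econ_rate` (default 13.5%, the middle of the 12–15% per-arm
range). Because the probability depends only on observed covariates, the
mechanism is MAR by construction — a property the test suite checks by
regressing the missingness indicator on the latent cost. Cognitive
dropout (default 15%) works the same way, removing visits from a random
post-baseline visit onward. What the generator does **not** emulate:
eligibility screening, recruitment dynamics, adherence, MNAR mechanisms,
per-window cost trends, or correlation between cognitive decline and
costs. Passing tests therefore demonstrate that the statistical machinery
is correct under MAR and under this cost model — not that real trial data
meet those assumptions.

## Costing

Four valuation rules cover the payer-perspective sources: `fixed_tariff`
(quantity × unit cost), `per_diem` (length of stay × daily rate),
`ddd_drug` (reimbursement price per unit × defined daily dose × treatment
duration), and `gamma_sampled` (per-event gamma draw with shape = m²/v,
scale = v/m moment-matched to an observed mean and variance — the rule for
components where only frequencies are recorded). DRG/procedure
nomenclature lookups are deliberately abstracted into the JSON-serialisable
tariff table.

Intervention pricing: PFA at €0.50 per capsule × 365.5 capsules/year × 3
years = €548.25; MI at a €40/h facilitator wage × 2.30 h per session ×
`mi_sessions_priced`. The default of 10 priced sessions reproduces a €920
per-participant MI cost; the full individual schedule (twice weekly in
month 1, weekly in month 2, monthly thereafter ≈ 46 sessions) is available
by overriding the parameter — group sessions are plausibly cost-shared,
which the 10-session default reflects. Intervention costs are added to
resource-use totals deterministically, so
`total_with = total_without + intervention` holds exactly per participant.
Costs are kept at full precision internally; reported tables round half-up
to whole euros.

## Descriptives

Cost tables are computed on complete-follow-up participants,
operationalised as: economic data available for the full horizon **and** a
completed final cognitive visit. Mean component costs carry BCa bootstrap
95% CIs (B = 2,000 by default): percentile intervals corrected for median
bias z₀ = Φ⁻¹(#{θ*_b < θ̂}/B) and for skewness via the jackknife
acceleration. A constant sample returns the degenerate interval with a
flag (the acceleration is undefined; z₀ is irrelevant). Between-arm
comparisons use the global Kruskal–Wallis rank test with mid-rank tie
correction (scipy's implementation; an independent rank-formula oracle and
the two-group rank-sum equivalence are asserted in the tests). On
one-sided calibration the BCa interval is markedly better balanced than
the normal-approximation interval for skewed cost-like data; two-sided
coverage of the two can be statistically indistinguishable at moderate n
because the normal interval's one-sided errors partially cancel — the test
suite therefore checks coverage and per-side calibration separately.

## Imputation

Missing 3-year cumulative totals (without intervention — the intervention
component is deterministic per arm) are multiply imputed by predictive
mean matching: per imputation, σ² is drawn from its scaled inverse
chi-square posterior and β from N(β̂, σ²(XᵀX)⁻¹); missing cases are
matched on predicted values to the k nearest observed cases and filled
with a uniformly drawn donor's observed outcome, so imputed values never
leave the observed support. Predictors follow the analysis plan: age
tercile, gender, arm, frailty, medical-history tercile (terciles on the
observed marginal, ties to the lower tercile). Defaults m = 20, k = 5 —
conventional values giving stable Rubin inference at these missing rates.
Pooling uses Rubin's rules with Barnard–Rubin degrees of freedom.

**Attrition check.** A Hausman-type quadratic form dᵀ(ΔV)⁻d compares the
complete-case GLM coefficients with the Rubin-pooled imputation-based
ones, ΔV being their covariance difference, with a chi-square reference on
rank(ΔV); when ΔV is indefinite the form is evaluated on its
positive-eigenvalue subspace (flagged). Two caveats are documented rather
than hidden: (i) ΔV overstates the variance of the contrast because the
two estimators are strongly correlated, so the check is conservative;
(ii) when the imputation model equals the analysis model, both estimators
share the same probability limit even under outcome-dependent (MNAR)
missingness, so the check has essentially no power against that
alternative. It is a consistency diagnostic, not an MNAR test — which is
also why MAR is an assumption, verified here only by construction of the
generator.

## Adjustment

**Effectiveness.** The composite Z standardises each test to the baseline
cohort mean/SD and averages the four; it is missing whenever any component
is missing. The trajectory model `z ~ arm * visit` (visits categorical) is
fitted by maximum likelihood — ML rather than REML so that likelihoods
remain comparable across fixed-effect specifications — with a participant
random intercept and the center term in one of three modes: `random` (a
center variance component; the fully specified model and the default),
`fixed` (center fixed effects — equivalent arm contrasts in a balanced
design at a fraction of the cost, used in the heavier test sweeps), or
`none`. A failed or boundary random-center fit falls back to `fixed`,
flagged. The adjusted ΔE is the arm × 36-month interaction contrast — the
difference-in-differences — because the outcome is change from baseline
and randomisation places the true effect entirely in the interaction;
including the arm main effect in the contrast would only add baseline
noise to a cross-sectional comparison.

**Costs.** A gamma GLM with log link is fitted to cumulative totals on the
imputation covariates plus baseline-Z terciles; exponentiated coefficients
are reported as relative risks with Wald CIs. Adjusted per-arm costs come
from marginal standardisation (predicting every participant under each
counterfactual arm and averaging) — the default because it targets the
population-averaged difference that belongs in an ICER numerator; arm
means of fitted values are available as an alternative (`mode="fitted"`).
Per-imputation increments are pooled by Rubin's rules, and the
deterministic intervention cost difference is added afterwards, making the
with/without decomposition exact. Zero totals (possible in synthetic data,
implausible in 3-year claims) are rejected by default; an explicit option
shifts them by half the smallest positive observed cost.

## Cost-effectiveness stage

The point ICER carries cost-effectiveness-plane semantics: NE (more
costly, more effective — the ratio is the price of a Z point), dominant
(cheaper, more effective), dominated, SW (cheaper, less effective — ratio
reported with a caution flag), and an explicit undefined flag at ΔE = 0;
no exceptions. The bootstrap resamples participants with replacement
within each arm (stratification preserves the randomised design; B =
1,000), recomputing arm-mean (ΔC, ΔE) per replicate in fast mode; when
multiply imputed datasets are supplied, replicate b resamples imputed
dataset b mod m, propagating imputation uncertainty into the cloud.
Re-estimating the GLM and mixed model inside every replicate is
intentionally avoided: at these sample sizes the adjusted and unadjusted
contrasts agree in expectation under randomisation, and the fast mode
keeps the bootstrap inside interactive budgets. The 95% confidence
ellipse is the χ²₂(0.95) Mahalanobis contour of the replicate cloud
(degenerate clouds flagged); the CEAC is the fraction of replicates with
positive net benefit λ·ΔE − ΔC over a €0–150,000 grid in €500 steps
(three times the €50,000 reference threshold) — always computed on the
net-benefit scale, never by averaging ratios, so negative-ΔE replicates
are handled correctly.

**Binary effectiveness.** A participant counts as "no aggravation" iff the
36-month composite change exceeds −0.3 (a 0.3-point decrease being the
minimum clinically significant decline, predictive of dementia); the
boundary value itself counts as aggravation by default (`strict=True`,
configurable). The per-arm percentage feeds the alternative ICER in € per
percentage point.

## Pipeline, seeds, problem sizes

`run_pipeline` chains the stages with per-stage seeds derived from one
master seed and records them in a JSON manifest sufficient to re-run
bit-identically. The base case imputes (m = 20); the sensitivity analysis
restricts every stage to complete-follow-up participants. Default problem
sizes — 380 participants per arm, B = 1,000 bootstrap replicates, m = 20
imputations — are the reference conditions of this design; the test suite
uses smaller cohorts for speed where the property under test allows it and
the full scale where it is the point (mixed-model contrast recovery, the
calibrated-pipeline check).

## Known limitations

- No QALY estimation (a composite cognitive Z is the effectiveness unit
  by design), no discounting over the 3-year horizon, no indirect or
  informal-care costs, no lifetime extrapolation.
- The attrition check's power limitation under MNAR is structural (see
  above).
- Fast-mode bootstrap does not re-fit the adjustment models per replicate;
  covariate-adjustment uncertainty in ΔC and ΔE is therefore reflected in
  the cloud only through the raw arm contrasts.
- The generator's MAR mechanisms and independence assumptions mean test
  results validate the machinery, not the behaviour of any real cohort.
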