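# Methods

This note documents the statistical machinery in `cadcea`: the models and
their assumptions, the synthetic-data generator and what it does and does
not emulate, the parameters that matter, and the package's numerical
choices.

## Study design being modelled

A two-arm quasi-experimental cohort of clinically stable people living
with HIV: 2049 participants under multi-month dispensing (MMD, control)
and 2040 under community ART delivery (CAD, intervention, served by 82
community action workers), surveyed at baseline and endline (~19 months
apart).  Outcomes are three binaries: ART adherence ("no" to all five
primary adherence items), good physical health (SF-12 PCS ≥ 50) and good
mental health (MCS ≥ 42).  Thresholds are inclusive — the category
definitions in the outcome tables (≥ 50 / ≥ 42) are taken as
authoritative over looser "higher than" phrasing, and the boundary case
is flagged in `measures`.  Analyses follow intention to treat: every
participant is analysed (and costed) under the original assignment and
the full arm size is the cost denominator.

## Synthetic cohort generator (`synth`)

The study's individual-level data are not deposited, so the generator is
a first-class component that emulates the data's statistical structure:

* **Covariates** are drawn per arm from the published socio-demographic
  marginals (site setting, age, gender, education, employment, family
  structure, HIV/ART duration, transport, travel time, comorbidity);
  household income and waiting time are log-normal around the published
  per-arm medians.  Arm imbalance is therefore reproduced by
  construction.
* **Outcomes** are generated on a latent log-odds scale:
  `logit p = c_{arm} + γ'x + u`, with a shared participant random
  intercept `u ~ N(0, 0.8²)` inducing the baseline–endline correlation a
  panel implies (no within-person correlation is published; 0.8 gives a
  tetrachoric-like correlation of ≈ 0.3).  The covariate loadings γ are
  free parameters (none are published): modest log-odds effects in the
  0.15–0.8 range wired to face-valid predictors (comorbidity and age
  against physical health, short ART duration against adherence, ...).
* **Calibration.** The arm intercepts, the endline time shift and the
  arm-by-time interaction are found by bisection so the *marginal*
  prevalences hit the published baseline/endline values exactly in
  expectation.  Calibrated this way, the implied conditional interaction
  odds ratios come out at ≈ 1.6–1.8 for adherence and physical health and
  ≈ 1.25 for mental health, consistent with the published effect
  estimates.  Explicit logit shifts can be supplied instead (the
  parameter-recovery tests use a fixed interaction OR of 1.6).
* **Scores and items** are generated consistently with the binaries:
  PCS/MCS are truncated normals on the correct side of 50/42; adherence
  items are all-"no" for adherent participants and itemwise draws with at
  least one "yes" otherwise.
* **Costs** are semicontinuous per-trip items in Riel: a point mass at
  zero (probability 0.90–0.97 for medical items, 0.08–0.15 for
  transport/food) plus a log-normal, medians matched to the published
  per-item medians (transport medians average the two waves: 9000 Riel
  control, 8000 intervention).  Visit counts are Poisson (means
  5.25/4.72) truncated at ≥ 1.  The programme ledger ships with the
  published USD items (CAW salary 235,260; training 6,007.37/4,733.30;
  meetings 9,055.03), entered already inflation-adjusted.
* **Dropout** is missing at random: `logit P(LTFU) = c_arm + δ'(baseline
  variables)`, with δ free parameters and `c_arm` calibrated by bisection
  to the published marginal rates (29.67% control, 20.29% intervention).
  Endline rows are deleted for selected participants; baseline rows never
  are.  MNAR mechanisms are deliberately out of scope.

What the generator does **not** emulate: item-level SF-12 scoring (scores
are drawn directly), clinic operations, viral load/CD4 trajectories,
COVID-19 shocks, and any dependence of dropout on unobserved endline
values.  Tests passing on this cohort therefore certify the *pipeline's*
statistical behaviour under its stated assumptions, not the study's
substantive conclusions on real data.

Randomness: one master seed; per-stage child generators are spawned from
`numpy.random.SeedSequence(seed)` in a fixed documented order, so each
stage is independently reproducible.

## Multiple imputation (`impute`)

Fully conditional specification with one chain per imputed dataset
(m = 10 by default).  Method dispatch by type: predictive mean matching
(PMM) for continuous variables, Bayesian-draw logistic regression for
binaries, proportional-odds/multinomial sampling steps for categoricals.
Within a sweep, variables are visited in ascending missingness fraction
(fixed tie-break by name); chains initialize missing cells by draws from
observed marginals.

PMM uses type-1 matching with k = 5 donors (the conventional default; no
donor-pool size is published): observed-row predictions use the ML
coefficient estimate, missing-row predictions use a posterior draw
(normal approximation, scaled-inverse-χ² residual variance), and each
missing row copies the observed value of a uniformly chosen donor among
the k nearest predicted means.  Because imputations are always members of
the observed support, the zero point mass of semicontinuous costs is
preserved without a dedicated two-part model.

Socio-demographics of LTFU participants carry forward from baseline (they
are assumed stable over the window) and are never imputed.  Predictors
are the socio-demographics plus baseline outcomes/costs plus the other
imputed endline variables; the visit count is imputed from
socio-demographics only.  Binaries derived from scores
(`good_physical_end`, `good_mental_end`) are recomputed from the imputed
PCS/MCS rather than imputed separately, which keeps the score and its
dichotomization consistent within every dataset.

A singular or separated step falls back to a marginal draw for that sweep
with a logged warning.  Convergence is summarized per variable from the
chain means over the final 10 sweeps: between-chain variance, within-chain
variance, and a potential-scale-reduction-style mixing ratio flagged at
1.2.  The study's endline missingness is *monotone* (all endline variables
missing for exactly the LTFU set), so the sampler stabilizes within a few
sweeps; the default of 50 sweeps is kept for fidelity, while the
acceptance script and simulation tests use 10 and 3 sweeps respectively —
a size choice documented here once and reflected in every reported run.

## Effects (`effects`)

Per imputed dataset, a single ML logistic model on the stacked
baseline+endline rows with arm, wave, arm×wave and outcome-specific
adjustment covariates (defaults follow the published adjusted models:
site setting/age/employment/ART duration for adherence, etc.; income
enters on the log scale).  The arm×wave coefficient is the adjusted
intervention effect ("AOR"); the published tables do not state the exact
parameterization, and this single-interaction-model reading is adopted
and tested.  Perfect separation on the inferential terms raises; an
extreme coefficient on a sparse covariate dummy only warns.

Marginal standardization: for stratum (arm, wave), all rows of that arm
get their indicators set counterfactually, covariates stay observed, and
predictions are averaged; under a saturated model this equals the raw
stratum proportion (tested as an exact identity).  The DiD is computed
*within* each imputation (with a delta-method variance that propagates
the covariance among the four strata through the single model) and the m
DiD values are pooled; the alternative — assembling the DiD from four
independently pooled strata — gives the identical point estimate (the
statistic is linear) with a conservative SE, and is available as an
option.

Rubin's rules: `q̄ = mean`, `W = mean(var)`, `B = var(q)` (ddof 1),
`T = W + (1 + 1/m)B`, `λ = (1+1/m)B/T`, FMI with the small-sample
adjustment, Barnard–Rubin degrees of freedom, t-based intervals.  FMI and
λ are checked against the 0.25 acceptability bound on every pipeline run.
Model selection (when requested) compares nested candidates to the full
model by likelihood-ratio test, keeping the smallest candidate with
p > 0.05 and breaking ties by BIC — parsimony first.

Limitations mirrored from the analysis being reproduced: no random
effects or GEE for the repeated measure (the two waves enter as stacked
rows), and parallel trends is untestable with two time points.

## Costing (`costing`) and decisions (`cea`)

Currency arithmetic is type-safe (`Money`): mixing Riel and USD raises.
Order of adjustment is fixed — inflate in the original currency by the
CPI ratio to the reporting date, then convert at 1 Riel = 0.00024 USD.
The CPI series is a config input (none is published); the shipped ledger
is already at the reporting price date, so its default CPI ratio is 1.

Participant out-of-pocket expenditure is the per-trip itemized total
(averaged over the two waves' reports) times the number of facility
trips.  Productivity uses the human-capital approach:
`trips × (2·travel + waiting hours) × wage`, doubled when a caregiver
came along; travel-time categories map to one-way hours
(0.25/1.25/5/10).  The wage rate defaults to 0.45 USD/hour — median
household income (~216 USD/month over ~30×8 hours ≈ 0.9 USD/hour per
household) split over roughly two earning adults — and is the single
knob that scales productivity costs; the exact published valuation lives
in unpublished supplementary material, so the parameter stays in config.

IPW: logistic propensity of assignment on the socio-demographic set,
fitted values clipped to [0.01, 0.95]; stabilized weights
(marginal/conditional probability) truncated at their empirical 99th
percentile *within each imputed dataset* (the alternative — a pooled
cap — is not distinguishable from the published description; per-dataset
truncation keeps datasets self-contained).  Weighted means use
`Σwc/Σw` with a linearized-ratio variance, pooled across imputations by
Rubin's rules, and scale to arm totals by the ITT denominator.

Perspectives: health-system = programme-payer ledger items only;
societal = health-system + participant/caregiver OOPE + participant
productivity, explicitly excluding community-worker OOPE and
productivity (their salary, transport and communication are already
health-system items — double counting otherwise).

Decisions: ICER with quadrant classification (dominant/dominated/
undefined — never a division by a zero effect); `INB = CET·ΔE − ΔC`,
a formula verified cell-by-cell against every published decision-table
entry before being frozen into the tests; cost-effective ⟺ INB ≥ 0.
Reports round half-up to 2 decimals; all internal arithmetic is full
precision (one published DiD, 0.11 for physical health, is only
reproducible from unrounded components — the pipeline never hard-codes
it).

## Problem sizes and numerical choices

* Full-scale runs (2049/2040, m = 10, 10 sweeps) drive
  `scripts/acceptance.py`; a run takes ~1–2 minutes on one CPU.
* Simulation tests use deliberately reduced sizes chosen for Monte-Carlo
  adequacy: interval-coverage of a true interaction OR 1.6 uses 50
  replicates at 500/arm (m = 5, 3 sweeps, adherence imputed); MCAR
  mean-recovery uses 20 replicates at n = 250-300.
* Bisection calibrations run to |Δ| < 1e-10 on the intercept; targets
  are validated attainable and error otherwise.
* The coverage test tolerates the known small attenuation from fitting a
  marginal logistic model to data generated with a random intercept
  (non-collapsibility); at these sample sizes the bias is well inside one
  standard error.
* Degenerate inputs have defined behaviour: empty donor pools raise,
  shrunken pools warn; single-level categoricals and all-missing
  variables raise in `describe_arms`; a zero-missingness table imputes to
  m identical copies; zero LTFU targets delete nobody.
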