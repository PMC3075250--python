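# Methods

## The profiling problem

Hospital mortality comparisons from administrative claims face three
coupled problems: case mix differs across hospitals, small hospitals have
wildly unstable observed rates, and the cohort itself must be constructed
from billing records under rules that decide who counts as an eligible
pneumonia admission and which hospital is accountable. This package
implements the full chain — cohort rules, risk adjustment, hierarchical
modelling, indirect standardization — and pairs it with a synthetic claims
generator whose ground truth makes every stage testable.

## Cohort construction

**Candidates** are inpatient claims carrying a qualifying pneumonia
diagnosis in any position (default code patterns `481`, `482.*`, `483.*`,
`485`, `486`, `487.0`; viral-pneumonia codes `480.0/480.1/480.2` behind a
config toggle, as is a hospice-exclusion placeholder). Exclusions are
evaluated in a fixed precedence so the audit tally attributes each dropped
admission to exactly one rule:

1. age at admission < 66 (age = (admission − birth)/365.25, floored);
2. fee-for-service enrollment not covering the full 12-month lookback
   through admission;
3. managed-care interval overlapping that window;
4. pneumonia present only as a secondary diagnosis;
5. discharged alive, not against medical advice, within the first day
   (`discharge − admission ≤ 1` with admission day 0). Deaths, AMA
   discharges and transfer-out dispositions are retained by this rule.

The precedence (demographic → enrollment → diagnosis → stay length) is a
design choice; the tally conservation invariant
`included + Σ excluded = candidates` holds on every input.

**Transfer linkage.** Consecutive same-beneficiary admissions merge into
one episode when the next admission starts no more than 1 day after the
previous discharge and both claims carry a qualifying pneumonia code (any
diagnosis position by default; a flag restricts to principal). Chains
longer than two merge transitively. The first admission supplies the index
hospital, index date, and outcome anchor; overlapping stays raise an
error rather than guessing a chain. Linkage runs after the admission-level
exclusions, so a receiving claim dropped by the first-day rule simply
shortens its episode.

**Outcome** is all-cause death within 30 days of the index admission
(`death ≤ admission + 30`); a missing death date is survival, a death date
before admission is a data error. One episode per beneficiary is then
sampled uniformly (episodes, not raw claims, are the sampled unit), and
the derivation/validation split is stratified by hospital with
`ceil(fraction · n)` per hospital to derivation, so single-case hospitals
are represented in derivation.

## Covariate assembly

Diagnosis/procedure codes map onto condition categories through an
ordered rules table (exact and prefix patterns) — the same aggregation
idea as Hierarchical Condition Categories, on a deliberately small
configurable vocabulary (~40 codes, 16 categories). A category indicator
is credited from (a) secondary/procedure codes on the index admission, or
(b) any encounter (inpatient, institutional-outpatient, physician) in the
half-open window `[t − 365 d, t)`; index-day encounters are not lookback,
preventing double-crediting. Categories flagged `complication_suspect`
(respiratory failure, shock, septicemia in the default mapping) may be
complications of the stay itself; they are credited from the index
admission only via the episode's *initial* claim, never the receiving
hospital. The flag is policy data in the mapping file, not code.

Candidate indicators with prevalence strictly below 1% are dropped
(a column at exactly the threshold is kept); demographics (age in years,
untransformed; female indicator) are never dropped. Collinearity is
screened by per-column VIF = 1/(1 − R²); exact collinearity is reported as
infinite with the dependent columns named.

Chart-abstraction matrices follow the missing-value-dummy method:
variables missing in more than 10% of records are excluded; each
remaining variable with any missingness contributes its base column
(missing filled with the reference value 0) plus a paired missing
indicator, keeping all cases under a missing-at-random assumption.

## Estimation

The hierarchical model is a logistic regression with a Normal random
hospital intercept. The marginal likelihood integrates each hospital's
effect with **adaptive Gauss–Hermite quadrature**: per hospital the
integrand is re-centered at its posterior mode (damped Newton, vectorized
across hospitals) and re-scaled by its curvature; 15 nodes by default,
1 node = Laplace. Optimization is L-BFGS-B over (mu, beta, tau) with
tau ∈ [0, 20]; a rare line-search failure from finite-difference noise is
polished by a derivative-free Nelder–Mead pass accepted only if it does
not worsen the objective. A tau estimate below 1e-4 is flagged as a
boundary fit (the model then coincides with the plain GLM) — flagged, not
an error. Standard errors come from the central-difference observed
information of the marginal log-likelihood; the tau SE is undefined at the
boundary. Hospital effects are reported as posterior modes with Laplace
posterior SDs, in a mean-zero parameterization with `mu` separate.

Correctness is checked two independent ways: a fixed 201-point
prior-centered quadrature oracle sharing no code with the fitter (they
agree to ~1e-11 at the fitted parameters), and lme4's `glmer`
(`nAGQ = 15`) on the same data (agreement to ~1e-3 on all parameters and
the log-likelihood). The original measure was fit with a
penalized-quasi-likelihood macro; quadrature was chosen here for accuracy
and testability, and PQL estimates are known to be attenuated for binary
outcomes with large cluster effects, so coefficient-level agreement with
PQL software is not expected to machine precision.

**Variable selection** is backward elimination under the ordinary logistic
GLM: repeatedly drop the covariate with the largest Wald p-value above the
exit threshold (default 0.01), refit, stop when all survivors are below.
Ties break by largest p, then smallest |z|, then column order, making
traces deterministic. Demographics can be forced in (off by default).
Binary columns that quasi-separate the outcome (an empty cell against y)
are screened out before elimination — their MLEs are infinite. The
selected columns are then re-estimated under the hierarchical model on the
full cohort, which is also the RSMR scoring fit.

## Standardization and intervals

`RSMR_h = (P_h/E_h) ×` national observed rate, with predicted deaths using
the hospital's empirical-Bayes intercept and expected deaths the national
intercept (random effect set to zero) on the hospital's own case mix.
Consequences that are asserted as invariants: alpha ≡ 0 forces every RSMR
to the national rate exactly; RSMR is invariant to duplicating the cohort;
the SD of RSMRs never exceeds the SD of observed hospital rates; and at a
fixed true deviation, |RSMR − national rate| grows with hospital volume
(less shrinkage with more data).

Intervals are percentile cluster-bootstrap: hospitals resampled with
replacement, the model refit per resample, and each hospital's replicate
RSMR computed from its own cases under the replicate's (mu, beta, tau) —
its replicate intercept is the posterior mode of its own cases under those
parameters, which stays well-defined when a hospital is drawn more than
once. The interval uses the replicates in which the hospital appears.
Re-running variable selection inside each replicate is available behind
the pipeline config but off by default. RSMRs are reported as percentages
with one decimal at the reporting layer only; internal values are
unrounded.

## Performance battery

* ROC area = concordance with ties at 1/2 (verified against an O(n²)
  all-pairs oracle up to n = 200).
* Generalized R² = 1 − exp(−2(ℓ_model − ℓ_null)/n); the max-rescaled
  variant is emitted alongside. The likelihood-ratio form is the default
  reported value; reported "adjusted" and "generalized" R² values are
  treated as the same statistic.
* Overfitting indices: logistic recalibration of outcomes on the frozen
  derivation risk score mu + x'beta; (0, 1) on the derivation data is an
  MLE identity and the no-overfitting benchmark; attenuated outcomes give
  slope < 1.
* Decile calibration: rank-based assignment into near-equal bins, tied
  predictions filling the lower decile first; the reported range is the
  top-minus-bottom observed rate.
* Pearson residuals (y − p̂)/√(p̂(1 − p̂)): mean, SD, count beyond ±3;
  fitted probabilities at 0/1 are flagged, not divided by.
* Group-level agreement between two rate sets (e.g. claims-based vs
  chart-based state rates): regression of one rate on the other weighted
  by hospitalization counts, plus a weighted correlation with Fisher-z
  large-sample SE = (1 − r²)/√(n − 3), and the paired-difference
  mean/median/max/range.

## The synthetic claims universe

The generator emulates the study conditions: hospital annual pneumonia
volumes are lognormal fitted to median 37 and quartiles 18/67 (the skewed
volume profile of US acute-care hospitals; a fixed-volume law serves
balanced estimator studies); hospital effects are Normal(0, tau²) with
tau = 0.4 by default; age is truncated-Normal(80.2, 8²) on [66, 110],
55.8% female; twelve condition categories have prevalences from 2% to 35%
with log-odds effects from −0.25 (asthma, an empirically observed
protective inversion in pneumonia cohorts) to +0.90 (metastatic cancer),
plus age (+0.04/year above 80) and sex (−0.10 female) effects. The default
national intercept −2.27 is calibrated so the *marginal* cohort mortality
sits at the ~15.1% unadjusted level of elderly pneumonia cohorts. Each
true condition emits a mapped code into the prior-year encounter tables
with probability 0.85 (and onto index secondary codes with probability
0.5); at emission probability 1 the covariate stage must recover the true
condition matrix exactly, and the tests assert that it does. Dates are
integer day offsets from a fixed epoch (day 0 = Jan 1 of the lookback
year); intervals are closed, matching claim semantics.

Exclusion-triggering records (managed-care overlap, truncated enrollment,
secondary-only pneumonia, first-day live discharge, under-age, transfer
chains at gap 1, readmissions at gap ≥ 2) are planted at configurable
rates — values below 1 are fractions of the cohort, values ≥ 1 exact
counts — and every planted record carries a truth label, so the cohort
audit can be checked for exact recovery. Planting modifies only
single-claim beneficiaries so one label corresponds to one admission.

What the generator does **not** emulate: comorbidity co-occurrence
(categories are independent given the hospital), false-positive coding
(codes are emitted only for true conditions), billing/payment fields, DRG
codes, and seasonal admission patterns. Passing tests therefore
demonstrate correctness of the machinery under the stated law, not
clinical realism of any particular coefficient.

## Numerical choices and degenerate inputs

* Mode-finding Newton steps are clipped to ±4 log-odds; convergence at
  gradient < 1e-11.
* Optimizer tolerances: ftol 1e-12, projected-gradient 1e-7, ≤ 200
  iterations.
* The one-per-patient sampler and all splits derive their streams from
  `SeedSequence([seed, stage-constant])`, so stages are independently
  reproducible and the whole pipeline is deterministic from one root seed.
* Empty hospitals make the RSMR undefined (error, not NaN); unknown
  hospital ids are an error rather than silently scored at alpha = 0.
* An empty selected-variable set or a degenerate validation half skips
  the validation recalibration with an explanatory report entry rather
  than failing the run.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to keep Monte-Carlo error
well inside the asserted tolerances: estimator recovery at 200 hospitals ×
50 patients (40 replicates), degenerate-limit and attenuation checks at
n = 50,000, selection operating characteristics at n = 20,000 over 20
replicates, stability across six 20,000-patient cohorts from one fixed
truth, and bootstrap behaviour at B ≈ 100 on 25 hospitals. The bootstrap
coverage check asserts a conservative floor (0.8 at nominal 0.95) because
with homogeneous hospitals the per-hospital coverage events are strongly
correlated and the observed fraction is far noisier than the nominal
level.

## Known limitations

* The random-effect distribution is Normal only; no nested/crossed
  structures, no full Bayesian posteriors.
* PQL non-equivalence (above): numbers from PQL-era software will differ
  slightly, especially for small hospitals and large tau.
* The synthetic vocabulary has ~40 codes; the real ICD-9 space has
  ~15,000 and 189 condition categories — the mapping machinery is the
  same, the clinical content is not.
* State-level chart-vs-claims comparison is exercised structurally on
  paired synthetic covariate views of one latent severity; no real chart
  abstractions are modelled.
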