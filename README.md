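# rsmrpipe

Claims-based hospital profiling for 30-day pneumonia mortality: from raw
admission and encounter tables to hospital **risk-standardized mortality
rates (RSMRs)** via a random-intercept hierarchical logistic model — with
the full surrounding machinery (cohort rules, transfer-episode linkage,
condition-category covariate assembly, backward elimination,
empirical-Bayes shrinkage, cluster-bootstrap intervals, and a validation
battery), exercised end-to-end on synthetic Medicare-style claims with
known ground truth.

## Who this is for

Health-services and outcomes researchers who want a transparent, testable
implementation of the CMS-style profiling methodology for condition-level
30-day mortality — either to study its statistical behaviour (shrinkage,
compression, stability) on simulated data, or to run the pipeline on their
own delimited claims extracts.

## The model

For patient *i* in hospital *h*, with case-mix covariates
*x*<sub>ih</sub> (age, sex, and condition-category indicators assembled
from the index admission and a 12-month lookback):

```
y_ih ~ Bernoulli(p_ih)
logit p_ih = mu + x_ih' beta + alpha_h,     alpha_h ~ N(0, tau^2)
```

* `mu` — national intercept; `beta` — patient-level log-odds effects;
  `alpha_h` — latent hospital effect, reported as the empirical-Bayes
  posterior mode (shrunk toward 0 in proportion to hospital volume).
* Estimation maximizes the marginal likelihood by **adaptive
  Gauss–Hermite quadrature** (default 15 points; 1 point = Laplace). An
  independent fixed 201-point quadrature oracle verifies the likelihood.
* Covariates are chosen by backward elimination under an ordinary
  logistic GLM (Wald exit criterion p > 0.01), then re-estimated under
  the hierarchical model.

Each hospital's RSMR is an indirect standardization:

```
P_h = sum_i expit(mu + x_i' beta + alpha_h)     (predicted deaths)
E_h = sum_i expit(mu + x_i' beta)               (expected deaths)
RSMR_h = (P_h / E_h) * national observed rate
```

A hospital whose intercept is shrunk to zero lands exactly at the national
rate; the spread of RSMRs is always narrower than the spread of raw
observed hospital rates. Percentile interval estimates come from a cluster
bootstrap that resamples hospitals and refits the model.

## Worked example

```sh
cat > example.yaml <<EOF
simulation:
  n_hospitals: 60
seed: 11
output_dir: example_out
EOF
rsmrpipe run --config example.yaml
```

prints

```
cohort n=2896 across 60 hospitals; national rate 17.2%
derivation AUC 0.653, R2 0.048, tau 0.450
```

and writes the artifacts (`cohort.csv`, `exclusions.csv`,
`covariates.csv`, `fit.json`, `rsmr.csv`, `report.json`) under
`example_out/`. The first RSMR rows:

```
hospital_id,n,observed_deaths,predicted_deaths,expected_deaths,rsmr
H0000,38,5,5.54,6.07,0.157
H0001,139,25,24.58,23.02,0.184
H0002,122,8,10.96,18.25,0.103
```

Reading H0002: its case mix would be expected to produce 18.25 deaths
under the national model, but the model predicts only 10.96 given the
hospital's own (favourable, volume-shrunk) intercept, so its standardized
rate, 10.3%, sits well below the 17.2% national rate even though the raw
rate (8/122 = 6.6%) is more extreme — that is the empirical-Bayes
compression at work.

Every stage is also available separately (`rsmrpipe simulate`,
`build-cohort`, `covariates`, `fit`, `rsmr`, `validate`, `compare`) and as
library functions (`rsmrpipe.generate_dataset`, `build_cohort`,
`build_candidate_matrix`, `fit_random_intercept`, `rsmr_table`, ...).

## Layout

| module | role |
| --- | --- |
| `rsmrpipe.synthetic` | claims generator with known truth; exclusion-case planting |
| `rsmrpipe.cohort` | inclusion/exclusion, transfer linkage, outcome, sampling, splits |
| `rsmrpipe.covariates` | code→category mapping, candidate matrix, VIF, chart matrices |
| `rsmrpipe.hglm` | logistic GLM, backward elimination, adaptive-quadrature HGLM, oracle |
| `rsmrpipe.rsmr` | predicted/expected deaths, RSMR, cluster bootstrap |
| `rsmrpipe.performance` | AUC, generalized R², overfitting indices, deciles, residuals, rate-set comparison |
| `rsmrpipe.io` / `pipeline` / `cli` | delimited-file schemas, end-to-end driver, CLI |

See `docs/methods.md` for the statistical details and design decisions.
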