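# synthcohort

Synthetic clinical cohorts you can analyze as if they were real — plus the
machinery to check how far you can trust that.

Hospitals hold electronic-medical-record extracts that researchers often
cannot touch before ethics approval. One way out is to hand the researcher a
*synthetic* cohort: a generated patient table with the same statistical
structure as the real extract but containing no real person's record. That
only helps if analyses of the synthetic table predict the analyses of the
real one. `synthcohort` implements both halves of that bargain for
structured (tabular) cohorts:

1. **Generation.** Categorical combinations rare enough to identify a
   patient are censored first (small-cell suppression at a configurable
   threshold *k*). A distribution-free multivariate model is then fitted —
   for every joint level of the categorical variables (missing values count
   as a level of their own), the continuous variables are summarized by
   their empirical quantile tables and a rank-based (normal-scores)
   correlation matrix, i.e. a stratified Gaussian copula over empirical
   marginals. Synthetic replicates are drawn from this model; under the
   default `exact` count mode every purely categorical statistic of a
   replicate equals the real cohort's value exactly, while continuous
   values are fresh draws confined to the observed support. A QC report
   compares marginals and all pairwise associations.

2. **Validation.** The harness repeats synthesis K times, re-runs each
   declared analysis on every replicate, and reports per estimand:
   **bias** (mean replicate estimate − real estimate), **stability** (the
   min-to-max range of those differences), and **containment** (the
   fraction of replicate estimates inside the real 95% CI; for survival
   curves, the fraction of time points where the mean replicate curve stays
   inside the real Greenwood band). Log scales are used for odds and hazard
   ratios.

The bundled estimator families cover the common observational-study
toolkit: subgroup proportions (Wilson intervals), 2×2 odds ratios (Fisher /
Woolf unmatched, Mantel–Haenszel with the Robins–Breslow–Greenland CI after
1:n propensity matching), Kaplan–Meier curves with Greenwood log–log bands,
multivariate Cox proportional hazards (Efron ties), and AIC-stepwise
logistic regression with interaction hierarchy reporting predicted risks at
a covariate profile. Seeded fixture simulators generate "real" cohorts with
known ground truth for five archetypal designs (prescription-omission
proportions, two proportional-hazards studies, a heavily imbalanced
imaging-risk contingency, and a drug × lab-value interaction study), so the
whole pipeline is testable without any protected data.

## Worked example

Simulate a 4,590-patient heart-failure cohort where admission blood urea
nitrogen (BUN) category carries true hazard ratios of 1.29 and 1.67, then
validate Cox and Kaplan–Meier analyses across five synthetic replicates:

```python
import synthcohort as sc
from synthcohort.estimators import EstimandSpec
from synthcohort.validation import run_validation, summarize_validation

cohort = sc.simulate(sc.make_preset("bun_adhf", seed=1))
specs = [
    EstimandSpec(id="hr", family="cox_hr", time="time_to_event", event="event",
                 covariates=("bun_cat", "high_bnp", "high_rdw", "low_sodium")),
    EstimandSpec(id="km", family="km_survival", time="time_to_event",
                 event="event", horizon=1095),
]
reports = run_validation(cohort, specs, k_privacy=5, K=5, seed=42)
print(summarize_validation(reports)[["estimand_id", "real_point", "bias",
      "range_low", "range_high", "containment"]].round(4).to_string(index=False))
```

```
       estimand_id  real_point    bias  range_low  range_high  containment
hr:bun_cat[30to39]      0.3639  0.0040    -0.0030      0.0159          1.0
  hr:bun_cat[ge40]      0.4635  0.0135     0.0049      0.0270          1.0
       hr:high_bnp      0.2473 -0.0013    -0.0060      0.0069          1.0
       hr:high_rdw      0.1430 -0.0042    -0.0139      0.0077          1.0
     hr:low_sodium      0.2513  0.0091    -0.0045      0.0196          1.0
                km      0.5412  0.0000     0.0000      0.0000          1.0
```

Reading the first row: the real-data log hazard ratio for BUN 30–39 vs
<30 is 0.364 (HR 1.44); across five synthetic replicates the mean estimate
sits 0.004 higher, individual replicates range from −0.003 to +0.016 around
the real value, and every replicate falls inside the real 95% CI. The
Kaplan–Meier three-year survival (0.541 here) reproduces exactly because
the survival estimate at the horizon depends only on categorical structure
regenerated at exact counts. Exponentiating: real HR(≥40 vs <30) = 1.59,
synthetic mean 1.61.

The same pipeline is scriptable from a shell:

```bash
synthcohort simulate --preset bun_adhf --seed 1 -o real.csv --schema-out schema.json
synthcohort censor -i real.csv -s schema.json -k 5 -o censored.csv --report censoring.json
synthcohort synthesize -i censored.csv -s schema.json --replicates 5 --seed 42 \
    -o synthetic/ --qc qc.json
synthcohort analyze -i synthetic/synthetic_001.csv -s schema.json -a analysis.yaml \
    -o estimates.json
synthcohort validate -i real.csv -s schema.json -a analysis.yaml -k 5 -K 1000 \
    --seed 42 -o report.json --summary report.csv
```

Exit codes: 0 ok, 2 usage, 3 schema/data, 4 estimation, 5 I/O.

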