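# Methods

## The generative model

`synthcohort` treats a cohort as a mixture over the cells of the full
cross-classification of its categorical and boolean variables. A missing
categorical value is a level of its own, so records missing a value form
their own subpopulation and the synthetic data reproduce that missingness
pattern; imputation is deliberately left to the analyst, as with real data.

Within each cell (stratum) the continuous variables follow a Gaussian
copula over empirical marginals:

* each variable's marginal is its sorted vector of observed values (an
  empirical quantile table) plus a missing fraction;
* dependence is a correlation matrix estimated on the normal-scores scale:
  within-cell mid-ranks are mapped through Φ⁻¹((r − ½)/m) and correlated
  pairwise-complete. For a Gaussian copula this estimates the latent
  correlation, related to Spearman's ρ by r = 2·sin(πρ/6). Pairwise
  estimation can break positive semidefiniteness, so eigenvalues are
  clipped at 1e−8 and the diagonal renormalized — a standard, deterministic
  repair.

Sampling draws a multivariate normal with the stratum's correlation and
pushes each coordinate through the empirical quantile function, linearly
interpolated between order statistics and clamped to the observed range.
Clamping is privacy-conservative: no synthetic value escapes the real
support, so outliers are never amplified. Missingness is overlaid per
variable as an independent coin at the stratum's missing fraction (the
stratum key already carries all categorical missingness structure; nothing
finer is modeled).

Two refinements:

* **Count modes.** `exact` (default) regenerates every stratum at its real
  count, which makes every purely categorical statistic of a replicate
  identical to the real cohort's — the behavior observed when no censoring
  is required. `multinomial` draws stratum sizes multinomially at fixed
  total, giving honest sampling variability for stability studies.
* **Small cells.** Below `small_cell_min` (default 10) records a
  correlation matrix is too unstable to estimate, so the cell's continuous
  variables are resampled independently from their marginals with a
  uniform jitter of half the mean gap between adjacent order statistics
  (clamped to the observed range). The jitter also prevents verbatim
  copying of a rare patient's lab values.

## Privacy censoring

Before any statistics are extracted, cells of the categorical
cross-classification with fewer than *k* records (default k = 5, the usual
small-cell-suppression convention; configurable, k ≥ 2) are suppressed:
while an offending cell exists, the variable with the most schema levels
among the cell's non-missing variables is blanked for the cell's records
(ties broken by schema order) and the scan repeats. Blanking high-cardinality
variables merges cells fastest and therefore destroys the least
information. Because a blanked pattern is itself a level, suppression can
cascade until a record's remaining pattern is shared by at least *k*
records or nothing censorable remains; the guarantee is that afterwards no
partially-observed pattern is held by fewer than *k* patients. Continuous
values are never touched here — their defense is the resampling above.

The per-variable censoring *rates* are not individually monotone in *k*
(blanking more of one variable at a stricter threshold can merge cells in a
way that spares another variable); the total censoring rate and the number
of records touched are monotone, and that is what the property tests
assert.

A practical consequence worth designing for: the tie-break prefers earlier
schema columns, so schemas should list quasi-identifying covariates
(demographics, comorbidity flags) *before* the analytic exposure and
outcome. The bundled imaging fixture does exactly this; with the exposure
listed first instead, k = 5 censoring of its sparse exposed-outcome cells
deletes most exposed cases and biases the odds ratio far outside the real
CI. This mirrors the general advice to query variables at the minimal
resolution needed.

## Estimators and interval conventions

One adapter per family, all complete-case, all deterministic given their
inputs (propensity matching is the only seeded step):

| family | estimate | 95% interval |
|---|---|---|
| proportion | successes/n | Wilson score |
| odds ratio (unmatched) | sample OR (Haldane–Anscombe 0.5 on empty cells), Fisher exact p | Woolf logit |
| odds ratio (matched) | Mantel–Haenszel common OR over matched sets | Robins–Breslow–Greenland |
| KM survival | product-limit at a horizon | Greenwood log–log band |
| Cox | one log-HR per coefficient, Efron ties | Wald |
| logistic risk | predicted risk at a profile after AIC stepwise | delta method |

These are the field-standard defaults; none is exotic. Odds and hazard
ratios are reported on the log scale, where sampling distributions are
near-symmetric and bias/range summaries are meaningful; the ratio itself
travels in `diagnostics`.

Propensity matching fits an unpenalized logistic model of exposure on the
declared covariates, then matches greedily 1:ratio without replacement on
the logit, processing exposed records in seeded random order. No caliper is
applied by default (one can be added); a control shortfall is recorded
rather than fatal, and complete non-overlap of the logit distributions is
flagged as separation.

Stepwise selection starts from the main-effects logistic model, considers
all pairwise interactions of the declared covariates, and moves
bidirectionally to the largest AIC improvement until none exists, under the
usual hierarchy rule (an interaction may enter only while both mains are
present; a main may leave only when unused by retained interactions). This
is the least surprising reading of "stepwise by AIC"; the trace of accepted
moves is returned for audit.

## The validation protocol

`run_validation` censors the real cohort, fits the synthesis model once,
draws K replicates (replicate seeds derive deterministically from the
master seed via a seed sequence; the matching seed is shared by the real
analysis and all replicates so identical inputs give identical matched
analyses), runs every estimand everywhere, and summarizes per estimand:
bias (mean replicate − real), stability (min/max of replicate − real), CI
containment, and — for survival curves re-evaluated on the union time grid
— the fraction of grid points where the mean replicate curve lies inside
the real band. An estimator failure on one replicate (e.g. non-convergence
on a small draw) is recorded and excluded, never fatal, so thousand-
replicate runs finish unattended. K defaults to 5 for interactive use;
bias studies use K = 1000.

Two exact algebraic laws anchor the harness: with the generator replaced by
the identity, every family returns bias 0, range (0,0), containment 1; and
under exact counts every uncensored categorical estimand has zero bias and
zero range for any K. Censoring-induced instability is therefore studied
under `multinomial` counts, where suppressing a small subgroup's sub-k
cells shrinks the subgroup and strictly widens its replicate range.

## Fixtures: what they emulate and what they don't

The five presets reproduce the statistical *skeletons* of archetypal
hospital studies — subgroup sizes in the thousands against hundreds,
proportional-hazards effects near 1.3 and 1.67 with three-year survival
stepping roughly 60/44/37% across lab categories, administrative censoring
at 180 days or 3 years, a ~700-vs-12,600 exposure imbalance with
exposure-dependent confounder prevalences, and a drug × albumin interaction
(slopes −0.8 and −1.2 per g/dL around a 3.5 g/dL center, drug main effect
1.5, drug prevalence 17.8%) that makes the drug riskier at low albumin.
Magnitudes are shape choices for realistic desk-scale simulation, not
reproduction claims about any institution's data.

Covariates are drawn independently within groups, baselines are Weibull
(shape 1 by default — exponential; any proportional-hazards baseline
serves for recovery tests), and there is no longitudinal structure, no
informative censoring, no informative missingness, and no coding noise.
Passing tests therefore demonstrate that the pipeline preserves marginals,
pairwise and stratum-conditional dependence, and estimator calibration
under clean generating processes — not that synthetic copies of messy real
extracts inherit those guarantees. High-dimensional joint structure beyond
pairwise correlation within strata is explicitly not modeled.

## Numerical and design choices

* Normal scores use mid-rank offsets (r − ½)/m; average ranks for ties.
* Cholesky factorization adds a 1e−10 ridge after PSD repair.
* Empirical quantile inversion interpolates between order statistics at
  positions (i − ½)/m and never extrapolates.
* Greedy matching resolves distance ties toward the lower-logit neighbor;
  matched-set labels are zero-padded strings, so set ordering is stable.
* Stepwise ties on AIC are broken lexicographically (action, then term) for
  determinism; an accepted move must improve AIC by more than 1e−9.
* Boundary proportions (0/n, n/n) clamp the Wilson interval to include the
  point estimate despite float round-off.
* Replicate seeds and all derived seeds stay below 2³¹.
* Degenerate inputs fail loudly: empty cohorts, zero events, empty risk
  profiles, and schema mismatches raise typed errors that the CLI maps to
  distinct exit codes; a failed replicate inside the harness is the one
  deliberate soft failure.

## Known limitations

* No synthesis of unstructured data (text, images) or of longitudinal
  event sequences; time enters only as continuous offsets from an index
  event.
* No formal privacy guarantee (k-anonymity certification, differential
  privacy) and no adversarial re-identification testing; censoring plus
  support-clamped resampling is a pragmatic defense, not a proof.
* Dependence between continuous variables is Gaussian-copula within
  stratum; tail dependence and higher-order interactions are not captured.
* Small strata fall back to independent resampling, so cross-variable
  dependence inside very rare subgroups is deliberately discarded.
* Complete-case estimation throughout; analysts who need imputation must
  apply it downstream, identically on real and synthetic tables.
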