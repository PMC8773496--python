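# Methods

This note documents the statistical procedures implemented in
`tamspatial`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Cohort preparation

Cell tables are read per core; cores with fewer than 10 cancer cells are
excluded (the background tolerance limit is meaningless below that), with
machine-readable exclusion reasons. When a patient contributes more than
one core, the core with the larger CD163+ TAM count is kept — which is why
the fixed stage order is read → QC → phenotype → deduplicate → metrics.
Ties are broken by lexicographically smallest core id so reruns are
deterministic. The circular window defaults to 600 μm diameter centered on
the centroid bounding box (grown if cells fall outside), since only the
core diameter is physically known.

## Background-referenced phenotyping (UTL)

The CD163 signal of cancer cells is treated as pure background. For a
background sample of size *n*, the one-sided non-parametric upper tolerance
limit with content *p* and confidence *γ* is the *r*-th ascending order
statistic, with *r* the smallest rank satisfying
`BinomCDF(r − 1; n, p) ≥ γ`; this is the classical order-statistic
construction (the *r*-th order statistic exceeds the population
*p*-quantile with exactly that binomial probability). Defaults:
*p* = 0.95, *γ* = 0.99.

- For *p* = 0.95, *γ* = 0.99 the nominal confidence is attainable only for
  *n* ≥ 90 (`1 − 0.95ⁿ ≥ 0.99`). Smaller cores (allowed down to the
  10-cancer-cell QC floor) use the sample maximum and are flagged
  `degenerate`, with achieved confidence `1 − pⁿ` — the only conservative
  option at those sizes.
- An alternative `quantile-table` mode selects ranks from a user-supplied
  (n, rank) table with linear interpolation on n (rounded to the nearest
  integer rank), for compatibility with published rank tables.
- Positivity is strict (`intensity > UTL`); ties have measure zero for
  continuous intensities.

The Monte-Carlo experiments (tests and `scripts/acceptance.py`) verify the
coverage guarantee directly: at n = 200 the selected rank is 197 with
nominal achieved confidence 0.9910, and the empirical confidence over
10,000 standard-normal background samples is ≈ 99.1–99.2%. The guarantee
is distribution-free, so the choice of a normal background in the
simulation is immaterial.

## Spatial metrics

Seven per-core quantities are computed from the marked point pattern:
`tam_count`, `tam_proportion` (of stromal cells), the 10th/25th/50th
percentiles of per-cancer-cell nearest-TAM distances, and the mean counts
of TAMs strictly within 12 μm ("adjacent", ≈ one cancer-cell diameter,
juxtacrine range) and 250 μm ("communicating", the longest distance over
which paracrine cytokine signalling is considered effective) of each
cancer cell.

Numerical conventions:

- Percentiles use linear interpolation between order statistics (the
  default of the major statistical environments), which keeps quartiles
  reproducible on small cores.
- Zero-TAM cores stay in the analysis: count metrics are 0 and all NND
  percentiles equal the 600 μm truncation value (the core diameter).
  Distances are defensively capped at the truncation even in nonzero-TAM
  cores; inside a 600 μm window this is a no-op.
- Both disc radii use strict `<`. No edge correction is applied — the
  metrics are deliberately raw per-core summaries, not estimates of a
  stationary process's summary functions.
- Nearest-neighbor queries and disc counts use k-d trees; the test suite
  pins them to brute-force all-pairs oracles at 1e−9 on patterns up to
  2000 cells.

## Association testing

Spearman correlations carry Fisher-z confidence intervals with standard
error `1/√(n − 3)` (the CI method is recorded in the result metadata since
several conventions exist). Group associations use the tie-corrected
Kruskal–Wallis test; dichotomized markers use Fisher's exact test — exact
hypergeometric enumeration for small r×c tables, seeded Monte-Carlo with
the simulation flag recorded otherwise. Age between two groups uses the
two-sample Wilcoxon rank-sum test (a paired signed-rank option exists, but
the comparison of age between two independent marker groups is a
two-sample problem). Holm's step-down adjustment is applied within each
declared family of tests; the family partition is configurable because no
single partition is canonical.

## Survival modelling

Cox models maximize the Efron-tie partial likelihood (lifelines backend);
the tie convention matters once bootstrap resampling duplicates patients.
Factor covariates are dummy-coded against fixed clinical reference levels
(grade 1, tumor size <2 cm, node negative, "HR+ compliant" for the 3-level
combined hormone-receptor/therapy-compliance factor; HR− tumors form their
own level because therapy compliance is undefined for them). Two covariate
presets exist: *parsimonious* (grade, combined hormone factor, node, size)
and *full* (adds age, race, radiation). Chemotherapy is not a covariate
because the intended cohorts are uniformly chemotherapy-treated; a constant
covariate raises an error rather than silently degenerate.

Proportional hazards are checked per term by scaled Schoenfeld-residual
score tests (rank time transform, α = 0.05); violating terms can be moved
into strata and the model refit, with event-free strata collapsed into the
reference stratum under a warning.

A private vectorized Newton solver (`_fastcox`) implements the same Efron
partial likelihood for the bootstrap loops, where a DataFrame-based fitter
would dominate the runtime; it is cross-checked against lifelines to
~1e−5 in the tests and flags quasi-separation (diverging or boundary
coefficients) instead of returning meaningless estimates.

## Survival-tree cutpoints

Candidate thresholds are midpoints between consecutive unique metric
values with at least `min_leaf = 7` observations on each side (and
`min_split = 20` overall — the conventional survival-CART defaults). The
split maximizing the two-sample log-rank statistic is selected; the sign
of the observed-minus-expected term fixes `direction`, i.e., which side is
the high-risk group. Log-rank maximization was chosen over
exponential-scaling deviance splitting because, for a single first split,
the two select near-identical thresholds while log-rank is transparent and
directly testable against an independent oracle.

Retention is decided by honest 10-fold cross-validation: each fold
re-derives its own best split on the training 90% and the one-split
model's held-out exponential (Poisson-offset) deviance is compared with
the no-split model. Re-selecting per fold matters: validating only the
full-data split would let the test folds leak into the selection and
retain spurious splits under the null. With this rule a pure-noise metric
prunes to the root in the clear majority of simulated datasets, while a
true threshold effect of HR 3 at n ≈ 300 is retained essentially always.

The bootstrap layer (B = 1000 by default) reports the median of the
per-resample thresholds, their 5th/95th percentiles as a 90% CI, and the
number of resamples whose tree pruned to the root (excluded from the
distribution — reported, not imputed). Seeds spawn one child stream per
resample, so enlarging B extends rather than reshuffles the sequence.
Dichotomization is strict (`high ⇔ value > cutoff`), with `direction`
inverting the labels for metrics (such as the median NND) where *small*
values are adverse. The combined 3-category marker encodes (1) low
communicating-TAM count with high median NND (reference), (2) low count
with low NND, (3) high count regardless of NND.

## Optimism correction and multiple imputation

For each of B = 500 resamples drawn with replacement: the cutpoint is
re-derived in the resample; the marker dichotomized at that cutpoint is
fitted in the resample (bootstrap performance) and in the original data
(test performance); optimism_b is the difference of the marker's log HRs.
The apparent log HR uses the cutpoint derived on the original data; the
corrected estimate subtracts the mean optimism. Replicates whose tree
prunes or whose fit separates are skipped and counted (a warning fires
past 20%).

The marker's contrast direction (which side of the cutoff is the flagged
group — "high" for count metrics, "low" for nearest-neighbor distances)
is a *fixed per-metric convention*, decided once per analysis, not
re-derived inside each resample. This matters: re-orienting every
replicate toward its own empirically high-risk side leaks the shared
patients' noise into the test-performance evaluation, making the test log
HR positively biased under the null and leaving residual inflation the
subtraction cannot remove. With a fixed direction the per-cohort signs
are symmetric under the null and the correction centers the estimate, as
the null simulations verify.

The corrected estimate's variance combines the Wald variance of the
apparent fit with the variance of the bootstrap performances across
replicates — the plug-in for the variability of the data-driven selection
itself. The sum double-counts the fit noise embedded in the bootstrap
spread, which is intentional: for a non-smooth select-then-fit pipeline
the naive Wald interval is far too narrow (simulations put its true-to-
claimed SE ratio near 1.6 independent of n), and the conservative
composition restores near-nominal coverage while erring wide where the
cutpoint is unstable.

Missing covariates are imputed by chained equations: binary covariates by
logistic regression, ordered factors (grade, size category) by
proportional-odds models (fitted by an analytic-gradient cumulative-logit
optimizer, with a multinomial fallback if the ordinal fit fails),
continuous covariates by Bayesian linear regression, and the
HR+-conditional therapy-compliance variable by logistic regression within
HR+ patients only. Every imputation model conditions on the other
covariates plus the event indicator and the Nelson–Aalen cumulative hazard
of the survival time — the standard way to keep imputation compatible with
a downstream Cox analysis. Parameter uncertainty uses the bootstrap
variant of chained equations (each univariate model is refitted on a
resample of the observed rows before drawing), with 10 sweeps and m = 40
datasets by default. The optimism correction runs independently per
completed dataset; per-dataset *corrected* log HRs are then pooled by
Rubin's rule (within + (1 + 1/m)·between variance) with the Barnard–Rubin
small-sample degrees-of-freedom adjustment. Pooling the corrected
estimates (rather than pooling optimism separately) follows the stated
order of operations of the procedure; the two orderings differ only in
third-order terms.

## Synthetic-data generator

The generator encodes the statistical structure the analysis assumes, not
any particular image set:

- **Cores.** Cancer cells come from a parent–offspring cluster process
  (5 uniform parents, Gaussian offspring sd 40 μm, restricted to the
  600 μm disc) mimicking tumor nests; CD163− stromal cells are uniform.
  True TAMs are uniform ("random"), Gaussian-displaced from randomly
  chosen cancer cells with sd 30 μm ("attracted"), or uniform conditional
  on being farther from cancer than the uniform median ("repulsed").
  Intensities are log-normal: background log-mean 2.0, log-sd 0.25, with
  a +1.0 log-shift (4 background sd) for true TAMs — large enough that
  phenotyping recovers labels with ≥95% per-cell accuracy, as the tests
  assert.
- **Cohorts.** One core per patient with TAM fraction uniform on
  [0, 0.30]; the designated metric (default: TAM count) is computed from
  the *true* labels. Survival times are exponential with rate
  0.0035/month × exp(β·1[metric > c] + covariate effects), defaults
  c = 25.5 and β = log 3, with uniform censoring on [24, 140] months
  giving roughly 60% events. Covariates follow realistic breast-cancer
  marginals (grade 20/45/35%, 45% node-positive, 75% HR+, …) with modest
  log-hazard effects (0.3–0.5). Missingness is MAR: per-covariate logistic
  rates (2–12%, highest for hormone compliance) depending on the
  always-observed age and node status. Ground truth is returned separately
  and never written into the CSVs the pipeline reads (a leakage guard is
  tested).

What passing these simulations does *not* show: robustness to staining
batch effects, segmentation errors, intensity spill-over between touching
cells, non-circular or partially folded cores, or informative censoring —
none of which the generator emulates.

## Problem sizes in the test suite

The statistical acceptance tests run at sizes chosen to give stable Monte
Carlo verdicts on a single CPU: 10,000 replicates for the UTL coverage
check; 200 random patterns up to 2000 cells for the oracle-equivalence
check; 100 cohorts of n = 400 (bootstrap B = 100) for cutpoint recovery;
200 null cohorts of n = 300 with B = 200 for the optimism check; and 50
cohorts of n = 300 with B = 200 and m = 5 imputations for end-to-end
effect recovery. Production defaults (B = 1000 cutpoint bootstraps, B =
500 optimism resamples, m = 40 imputations) remain as stated above.

## Known limitations

- The exact-binomial UTL rank can differ by ±1 from published quantile
  tables that tabulate approximate ranks; the table mode exists for exact
  compatibility when such a table is supplied.
- The single-split survival tree is intentionally not a general CART: no
  multi-way or multi-covariate trees, and no p-value correction for
  maximally selected statistics (optimism correction is the chosen remedy).
- Harrell-style optimism correction assumes the selection procedure
  behaves comparably in bootstrap resamples and the original sample;
  duplicated patients make resamples slightly "easier" for the log-rank
  search, so a small residual bias remains at small n (visible as mild
  conservatism in the null simulations).
- The imputation engine targets this covariate set; it is not a general
  MICE replacement (no predictor selection, no passive imputation beyond
  the combined hormone factor).
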