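# tamspatial

Spatial analysis of CD163+ tumor-associated macrophages (TAMs) in multiplex
immunofluorescence images of breast-cancer tissue-microarray (TMA) cores,
with internally validated survival modelling of the derived biomarkers.

## The problem

M2-like (CD163+) macrophages suppress anti-tumor immunity, and both their
density and their physical proximity to cancer cells carry prognostic
information. Manual enumeration by pathologists is slow and subjective.
Given segmented cell tables — one row per cell with centroid coordinates
(μm), a cancer/stromal compartment label and a CD163 mean intensity —
`tamspatial` provides an objective, operator-independent pipeline:

1. **Phenotyping.** Cancer cells do not express CD163, so their measured
   signal is background. Each core's background sample defines a
   non-parametric **upper tolerance limit** (UTL) with content *p* = 0.95
   and confidence *γ* = 0.99: the smallest order statistic X₍ᵣ₎ such that
   P[Binomial(n, p) ≤ r−1] ≥ γ. Stromal cells whose CD163 intensity lies
   strictly above the per-core UTL are called CD163+ TAMs.
2. **Spatial metrics.** Each phenotyped core is a multitype marked point
   pattern (marks: cancer / CD163+ TAM / CD163− stromal) in a 600 μm
   circular window (sampled area 0.28 mm²). Seven per-core metrics:
   TAM count, TAM proportion of stromal cells, the 10th/25th/50th
   percentiles of cancer-to-TAM nearest-neighbor distances (truncated at
   600 μm; zero-TAM cores report the truncation value), and the mean
   number of TAMs within juxtacrine (<12 μm) and paracrine (<250 μm)
   range of a cancer cell.
3. **Dichotomization.** Each metric is split at a data-driven threshold:
   the first split of a survival tree (log-rank maximization with 10-fold
   cross-validated pruning), bootstrapped (B = 1000); the median bootstrap
   threshold is the cutoff and the 5th/95th percentiles its 90% CI.
4. **Internal validation.** The hazard ratio of the dichotomized marker in
   univariable or multivariable Cox models of progression-free survival is
   corrected for selection optimism: the cutpoint search is repeated inside
   each of B = 500 bootstrap resamples, and the mean difference between
   resample ("bootstrap") and original-data ("test") log HRs is subtracted
   from the apparent log HR. Incomplete clinicopathologic covariates are
   handled by chained-equations multiple imputation (m = 40) and Rubin's
   combining rule.

Because no public cell-level dataset accompanies this design, the package
ships a first-class synthetic-data generator (`tamspatial.synthetic`) that
produces cores and cohorts with known ground truth (true TAM labels, true
cutpoint, true log HR), which the test suite uses to verify every stage.

## Worked example

```python
import numpy as np
from tamspatial.synthetic import CohortGenSpec, generate_cohort
from tamspatial.model import OptimismCorrectedCox

# 300-patient synthetic cohort; true threshold 25.5 on the TAM count,
# true hazard ratio 3 above it, MAR gaps in the clinical covariates
patients, cores, truth = generate_cohort(CohortGenSpec(n_patients=300), seed=7)

model = OptimismCorrectedCox(patients, "tam_count", covariate_preset="parsimonious")
res = model.fit(B_cutpoint=200, B_optimism=200, m=5, seed=11)
print(res)
print(res.summary().T)
```

Output:

```
<OptimismCorrectedCoxResults tam_count: cutoff=27.5 (high-risk), HR=2.22 [1.33, 3.70]>
metric                tam_count
covariates         parsimonious
cutoff                     27.5
cutoff_ci90_low            25.5
cutoff_ci90_high           41.5
direction                  high
hr_apparent            2.469538
mean_optimism_log      0.107028
hr_corrected           2.218881
hr_ci_low              1.329687
hr_ci_high             3.702703
p                      0.002472
m_imputations                 5
```

The bootstrap cutpoint (27.5 TAMs per core, 90% CI 25.5–41.5) brackets
the generator's true threshold of 25.5; the apparent hazard ratio (2.47)
is shrunk by the estimated selection optimism (0.107 on the log scale) to
a corrected 2.22, whose 95% CI — widened to account for the uncertainty of
the data-driven dichotomization — covers the true hazard ratio of 3.

The same analysis runs from the shell:

```bash
tamspatial simulate --n-patients 300 --seed 7 --out cohort/
tamspatial run --config config.json
```

where `config.json` names the cell/clinical CSVs, seeds and bootstrap sizes.

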