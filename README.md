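# milsurv

Attention-based multiple-instance survival analysis for whole-slide
histology.

## The problem

Resected pancreatic ductal adenocarcinoma has a dismal and heterogeneous
prognosis, and the decision for adjuvant therapy rests on a handful of
clinical variables (grade, nodal status, resection margins). A routine
H&E/HES diagnostic slide contains far more information than those
variables, but it arrives as a gigapixel image with only one label per
patient — a censored survival time. `milsurv` implements the weakly
supervised pipeline for exactly this setting:

1. **Tiling & preprocessing** — the slide is cut into non-overlapping
   402 px tiles, tiles with more than 2/3 white background are removed,
   and stain appearance is standardized by Macenko normalization
   (OD transform, SVD stain estimation, concentration rescaling to a
   reference profile).
2. **Phenotype clustering** — tile features (pluggable extractor; a
   deterministic built-in descriptor or a pretrained CNN adapter) are
   grouped by k-means into k = 10 morphology "phenotypes".
3. **Attention-MIL survival model** — a shared (Siamese) per-instance
   network embeds each phenotype's tiles, mean-pools them, and a
   trainable attention mechanism aggregates the phenotype embeddings
   into one patient representation whose linear readout is a risk score.
   Training minimizes the negative log Cox partial likelihood

   `L = − Σ_{i: event} [ r_i − log Σ_{j: t_j ≥ t_i} exp(r_j) ]`

   (Breslow ties, full-cohort batches, exact risk sets).
4. **Risk stratification** — the continuous score is dichotomized at the
   cut-point maximizing the standardized log-rank statistic (maximally
   selected rank statistics, permutation-calibrated p-values), and the
   training cut-point is transferred unchanged to validation cohorts.
5. **Survival analysis** — Kaplan–Meier curves with Greenwood bands,
   log-rank tests, univariate/multivariate Cox models (HR, 95% CI, p per
   term), likelihood-ratio comparison of the clinical model against
   clinical + image score, and subgroup analyses.
6. **Attention maps** — per-tile heatmaps (tiles inherit their
   phenotype's attention weight) for interpretability.

Because the real cohorts behind such studies cannot ship, the package
includes a first-class synthetic-data module: stained toy tiles with a
known generating stain matrix, and patient-level feature-bag cohorts in
which phenotype composition drives a Weibull-baseline proportional
hazard with configurable clinical effects and calibrated censoring.
Every stage is tested against this ground truth.

## Worked example

```python
import numpy as np
from milsurv import (generate_cohort, phenotype_effect_pattern,
                     cluster_phenotypes, bags_from_cohort,
                     ModelConfig, train_ensemble, concordance_index,
                     maxstat_cutpoint, transfer_threshold, logrank_test)

# a 200-patient cohort: 10 phenotypes, log-hazard effect scale 2, 30% censoring
beta = phenotype_effect_pattern(10, 2.0)
cohort = generate_cohort(200, K_true=10, d=16, beta_phenotype=beta,
                         censor_rate=0.3, seed=0)

# split, cluster on the training portion only, build bags
idx = np.random.default_rng(1000).permutation(200)
tr, te = idx[:150], idx[150:]
X_train = np.concatenate([cohort.features[cohort.patients[i]] for i in tr])
_, clustering = cluster_phenotypes(X_train, k=10, seed=0)
bags = bags_from_cohort(cohort, clustering)

# train the attention-MIL ensemble and score held-out patients
cfg = ModelConfig(k=10, d=16, epochs=30, seed=0)
model = train_ensemble([bags[i] for i in tr], cohort.times[tr],
                       cohort.events[tr], cfg, n_members=3)
risks = model.predict_many([bags[i] for i in te])
print("held-out concordance:",
      round(concordance_index(risks, cohort.times[te], cohort.events[te]), 3))

# dichotomize on training scores, transfer the cut-point, test separation
res = maxstat_cutpoint(model.predict_many([bags[i] for i in tr]),
                       cohort.times[tr], cohort.events[tr], seed=0)
labels = transfer_threshold(res, risks)
lr = logrank_test(cohort.times[te], cohort.events[te], labels)
print("cutpoint:", round(res.cutpoint, 3), " maxstat p:", res.p_value)
print("validation log-rank p:", float(f"{lr.p_value:.2e}"))
```

Output:

```
held-out concordance: 0.778
cutpoint: 0.619  maxstat p: 0.000999000999000999
validation log-rank p: 2.36e-05
```

Held-out concordance 0.78 means the image-based score correctly orders
~78% of comparable patient pairs by event time — close to the ceiling of
the generating hazard on this cohort. The maxstat p-value (permutation,
multiplicity-adjusted) says the training-set split is far beyond chance,
and the transferred threshold still separates the held-out patients
(log-rank p ≈ 2e-5), the external-validation pattern the pipeline is
designed to test.

An end-to-end run (simulate → cluster → train with 5-fold CV model
selection → stratify → evaluate → heatmap, with caching and a
reproducibility manifest) is one call:

```python
from milsurv import RunConfig, run_pipeline
result = run_pipeline(RunConfig(seed=1), "runs/demo")
print(result.summary)     # cutpoint, HRs, log-rank p, medians per group
```

or `milsurv run --seed 1 --outdir runs/demo` from the shell (see
`milsurv --help` for the tile/filter/normalize/cluster/stratify
commands).

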