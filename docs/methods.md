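# Methods

`milsurv` implements a tile-based prognostic pipeline for resected
pancreatic ductal adenocarcinoma (and structurally similar settings): a
whole-slide image is reduced to a bag of tile features, the bag is
partitioned into morphology phenotypes, and an attention-guided
multiple-instance network trained with a Cox partial-likelihood loss emits
one scalar image-based prognostic (IBP) risk score per patient. The score
is dichotomized by a maximally selected log-rank statistic and evaluated
with standard survival models, alone and combined with clinical
covariates. This note records the model, its assumptions, the tunable
parameters, and the design choices that were genuinely open.

## Tile preprocessing

Slides are cut into non-overlapping `tile_size = 402` px tiles (0.5 µm/px
is carried as metadata only); partial edge tiles are dropped rather than
padded, so tiling is a partition of the retained area. A tile is discarded
when *more than* 2/3 of its pixels are white; a pixel is white when all
three 8-bit channels exceed 220. The 220 threshold is a standard
tissue-mask heuristic and a config knob; the 2/3 rule is strict
("greater than"), so a tile at exactly 2/3 is kept.

Stain normalization follows Macenko: optical density `OD = -log10((I+1)/256)`
(the +1 avoids log 0), tissue pixels = those with any channel above
`beta = 0.15` OD; the two stain directions are the 1st and 99th angular
percentiles (`alpha = 1`) of the tissue cloud projected on its top-2
SVD plane. Columns are unit-norm, non-negative, ordered hematoxylin-like
first (larger red-channel OD). Per-pixel concentrations come from an
exact closed-form two-variable NNLS; robust maxima are 99th percentiles.
A fixed, documented reference profile ships with the package so
normalization is reproducible without a reference slide; any profile can
be loaded from JSON instead. Angular percentiles use inverted-CDF
quantiles, which makes the estimate exactly invariant under pixel
duplication and ordering.

Assumption to note: a two-stain model. Saffron (HES) is not modelled
separately; on H&E-like synthetic data this is exact, on real HES slides
the third stain folds into the two estimated vectors.

## Phenotype clustering

Tile features come from a pluggable extractor. The built-in descriptor
(4x4 block-mean grayscale + 8-bin per-channel histograms, d = 40) is
deterministic and dependency-free; a pretrained CNN (e.g. VGG16
penultimate activations) plugs in through `register_extractor` with the
same contract. Features are z-scored per dimension on the fitted
population, then k-means (`k = 10`, k-means++ init, seeded) is fit ONCE on
the training population; centroids and scaler are frozen and validation
tiles are assigned to the nearest frozen centroid. Global (not per-slide)
clustering keeps the phenotype vocabulary comparable across patients,
which the attention weights and heatmaps presuppose.

## The attention-MIL survival network

Per patient: every tile feature vector passes through one shared
two-layer ReLU perceptron (d -> 64 -> 32); instance embeddings are
mean-pooled within each phenotype cluster; a tanh scoring network
(attention dim 32) gives one score per non-empty cluster; a softmax over
the non-empty clusters (empty clusters get exactly zero weight) produces
attention weights; the patient embedding is the attention-weighted sum
and a linear head maps it to a scalar risk. Risk is on the log-relative-
hazard scale with the convention larger = higher hazard; the "high score =
good outcome" direction seen in applications is a downstream label, never
assumed.

Training minimizes the negative log Cox partial likelihood with Breslow
tie handling (log-sum-exp stabilized), over full-cohort batches so risk
sets are exact. The network is small enough that plain numpy with
hand-derived gradients (checked against central finite differences in the
test suite) trains a 200-patient cohort in about a second on one core;
the optimizer is Adam (lr 1e-2).

Two regularizers are essential, not cosmetic. A Cox loss on a full batch
of a few hundred patients can be driven toward perfect separation of the
training ranks, and a flexible bag-level function will happily memorize
each patient's bag signature (training C ~0.99, held-out C collapsing
toward 0.65 in our simulations). The defaults are:

* `weight_decay = 1e-3` (L2 on all weights);
* `instance_jitter = 1.0`: fresh Gaussian noise added to every instance
  feature each epoch, emulating re-sampling the tiles of the slide. The
  unit default matches the within-phenotype feature spread of the
  synthetic generator; for other feature spaces it should be set relative
  to the within-cluster spread.

The recommended estimator is a small ensemble (`train_ensemble`,
3 members) over network initializations; member risks are standardized by
their own training-risk mean/sd before averaging, so no member dominates
through arbitrary scale.

A representational limit worth knowing: mean pooling normalizes away the
*absolute* share of the bag assigned to each cluster, so the network
cannot read cluster proportions directly. What it can read is which
phenotypes are present and the within-cluster mixture composition that
imperfect clustering induces (a patient's cluster-c mean shifts toward
the phenotypes contaminating cluster c in proportion to their share).
This is the channel the trained model actually exploits, and it bounds
achievable concordance below the oracle that sees true proportions.

Model selection mirrors the study design: patient-level, event-stratified
5-fold cross-validation over an epoch grid (10–80 by 10), with a 20%
internal test portion held out before CV and touched once. Epoch-grid
values are evaluated as snapshots of a single training run per fold. The
selection metric is Harrell's concordance: "accuracy" is undefined for
censored outcomes, and concordance is the standard discrimination measure
in that position.

## Risk stratification

The continuous risk is dichotomized at the cut-point maximizing the
absolute standardized two-group log-rank statistic over candidate
midpoints between consecutive distinct scores whose low-group proportion
lies in [0.1, 0.9]. Exact statistic ties resolve to the smallest
candidate. Because the maximum over correlated candidates inflates naive
p-values, the default inference is a permutation test (default 1000
permutations, each re-maximized); the Lausen–Schumacher (1992) asymptotic
approximation is available as a cheaper option. The training cut-point is
transferred to validation cohorts unchanged — no re-optimization, empty
groups permitted with a warning. A score exactly at the cut-point is
"low" (cut-points are midpoints, so this arises only with transferred
thresholds).

## Survival analysis

Kaplan–Meier uses the product-limit estimator with Greenwood variance on
the log-survival scale (`S * exp(±1.96 se)`); the median is the earliest
time with estimate ≤ 0.5, flagged undefined when never reached. The
log-rank test sums observed-minus-expected events with hypergeometric
variance; for two groups the chi-square is exactly the square of the
standardized statistic used in cut-point search (shared kernel).

Cox fits default to Efron tie handling (delegated to lifelines); a
Breslow Newton–Raphson built on the package's own partial-likelihood
kernel is available (`ties="breslow"`), converging at max |Δβ| < 1e-9
within 100 iterations with step halving. Breslow is also the tie rule
inside the training loss (cheap, standard for deep survival losses); the
reported fits use Efron for accuracy under ties — a deliberate, documented
divergence. Rank-deficient designs raise an error naming a collinear
subset; monotone likelihood (separation) flags the fit instead of
diverging silently. Categorical covariates are coded against the first
sorted level, matching the reference-row layout of clinical Cox tables.

The combined clinical + image model screens each clinical covariate by
its univariate likelihood-ratio p (threshold 0.05), fits clinical-only
and clinical + IBP-group models, and compares them by likelihood ratio.
Model comparison is by LRT plus concordance, the well-defined counterpart
of informal "AUC comparison" for censored outcomes. Subgroup analysis
fits the IBP effect per stratum, skipping event-free strata with a
warning.

## Attention maps

Attention is defined per phenotype cluster, so per-tile maps are
piecewise-constant by cluster: each tile inherits its cluster's weight.
Raw weights are preserved in the TSV export (lossless round-trip); for
display they are min-max rescaled per slide. Rendering is pure array
work (one rectangle per kept tile, absent tiles transparent, high
attention = blue by default), so identical inputs give bit-identical
files.

## Synthetic data

The generator replaces cohorts that cannot ship. Two parts:

**Tiles.** `I = 255 * 10^(-S c)` with unit-column stain matrix `S` and
per-pixel concentrations uniform in [0.02, 1.5] per stain (the near-zero
minimum lets near-pure single-stain pixels occur, which anchors the
angular extremes Macenko estimation relies on); an exact
`round(white_fraction * n_pixels)` count of pure-white background pixels.

**Cohorts.** Per-phenotype features are isotropic Gaussians with pairwise
mean separation 4 sd (a controllable difficulty dial). Each patient's
slide composition has a random support of 1–3 of the K phenotypes with
near-even proportions on the support (Dirichlet(8)) — slides dominated by
a few morphologies of comparable extent. Bags hold 100–300 tiles (real
slides carry tens of thousands; hundreds keep desk-scale runtimes while
leaving the cluster-embedding channel usable). The hazard is
`h0(t) exp(beta_phenotype · proportions + Σ clinical effects)` with
Weibull(shape 1.3, scale 20 months) baseline — median ~15 months and a
gently increasing hazard, in the range reported for resected PDAC; event
times are inverse-transform sampled, so at zero effects the marginal is
exactly the configured Weibull. `phenotype_effect_pattern(K, 2.0)` gives
a zero-mean coefficient vector with sd 2 — "effect scale 2" on the
log-hazard. Clinical covariates are Bernoulli(1/2) indicators with stated
log-HRs. Censoring is independent exponential with the rate solved
numerically (Brent) so the expected censored fraction hits the target
(default 0.3) for the realized event times; fixed administrative
censoring is a config alternative. All randomness flows through one
seeded generator per call; fixed seeds give bit-identical cohorts (the
only caveat is BLAS-dependent last-bit float variation in downstream
training, not in the generator itself).

What the generator does *not* emulate: spatial structure within slides,
staining artefacts, scanner batch effects, informative censoring,
correlated clinical covariates, or any real tissue morphology. Passing
tests therefore demonstrate that the machinery recovers planted structure
under the stated model — not clinical performance on real slides.

## Problem sizes and numerical choices

Simulation studies use cohorts of n = 200 (recovery; 10 replicates),
n = 400 (clinical-effect coverage; 50 replicates), n = 60–120 (null
calibrations; 200 replicates), and 120 + 120 train/validation pipelines
(10 replicates) — sizes at which every study runs in minutes on one core
while Monte-Carlo error stays well inside the asserted margins.
k-means uses 10 restarts; Cox Newton tolerance is 1e-9; the permutation
p-value uses the add-one estimator (1+#{≥obs})/(1+B), which is valid and
never exactly zero. Degenerate inputs raise typed errors (insufficient
tissue, rank-1 stain clouds, eventless cohorts, constant scores,
rank-deficient designs) rather than returning silent numbers.

## Known limitations

* No GPU path and no pretrained CNN weights are bundled; the extractor
  seam accepts one but desk-scale tests never download anything.
* The two-stain OD model; see above.
* Attention maps are piecewise-constant per cluster by construction —
  smoother per-patch maps would require per-instance attention, which
  this model does not define.
* The Lausen–Schumacher p-value is an asymptotic approximation, kept as
  an option only; inference defaults to permutation.
* Multi-slide patients are pooled into one bag by default; a per-slide
  mode exists behind a flag because the right aggregation is genuinely
  ambiguous.
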