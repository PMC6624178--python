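# Methods

## The score

For a dataset X (n samples × p features) with labels y over C classes, the
data is split into C + 1 (sub)datasets: the pooled matrix and one matrix
per class. Each is independently centered, embedded into k components and
reconstructed back into feature space; squared residuals are aggregated
column-wise. The score of feature j is the pooled per-feature error minus
the sum of the class-wise per-feature errors,

    score_j = Recon_all(F_j) − Σ_{c=1..C} Recon_c(F_j),

and the dataset-level score Σ_j score_j equals the pooled total error minus
the summed class-wise total errors by construction (the per-feature values
are an exact additive decomposition; a test asserts this to 1e-8 relative).
The analogy driving the construction: reconstruction error after lossy
compression behaves like entropy (complex data compresses badly), so the
pooled term stands in for H(X), the class-conditional term for H(X|Y), and
the difference for the mutual information I(X;Y).

Properties that follow and are enforced by tests:

- With a single class the two terms cancel feature by feature (scores are
  zero to 1e-10).
- Scores are equivariant under feature permutation and invariant under
  sample reordering (linear backend, exact up to 1e-8).
- Scores may be negative and are reported as-is. In particular, with the
  default per-class *mean* aggregation and C classes, the class-wise term
  is a sum of C per-class means, so well-behaved noise features sit near
  1 − C (on the standardized scale) rather than near 0. Only the induced
  ranking is consumed downstream; no flooring is applied.

## Embeddings and reconstruction

- **linear-pca** — PCA; reconstruction is the rank-k expansion about the
  column means. For centered data the total residual equals
  (n−1)·Σ_{i>k} λ_i of the sample-covariance eigenvalues, which the tests
  use as an independent oracle.
- **kernel-rbf / kernel-poly** — kernel PCA (RBF; polynomial of degree 3).
  Kernel PCA has no exact inverse, so the pre-image is approximated by a
  ridge-regularized *linear* map from the k embedded coordinates back to
  the centered input space, fitted on the embedding's own training data
  (regularization `preimage_ridge`, default 1e-3). This is deterministic
  and cheap; it is an approximation, and on nearly linear data its
  absolute error is a small multiple of the linear-PCA residual (a fixture
  test bounds it at 10×) rather than equal to it. Exact iterative
  pre-image optimization is out of scope.
- `rbf_gamma="auto"` sets the RBF width to 1/(p · var(X)) of the data being
  fitted — scale-free, evaluated per (sub)dataset since each subset is
  embedded independently. The polynomial kernel uses the library defaults
  (gamma = 1/p, coef0 = 1).
- The requested k is capped per (sub)dataset at its feasible maximum
  (min(k, n−1, p) for PCA, min(k, n−1) for kernel PCA) and recorded in
  `effective_components_`; class subsets smaller than a Cmin-derived k
  would otherwise make the published selection protocol unrunnable.
- `standardize=True` (default) z-scores every feature on the *full*
  dataset and applies the same scaling to every class subset, keeping
  pooled and class-wise errors commensurable across feature scales.
  Whether the original experiments scaled features is unknown; the flag
  exposes both readings.

## Aggregation

`aggregation="mean"` (default) aggregates squared residuals per feature as
mean squared error, matching the benchmark protocol's stated error measure;
`"sum"` keeps raw summed squares, the scale on which the two-feature
simulation magnitudes (hundreds over 500 samples) are reported. The ranking
is usually unchanged between the two; both are exposed.

## Component-size selection and the CV benchmark

Cmin is the sample count of the smallest class in the training data. The
candidate sizes are {1, Cmin/4, Cmin/2, 3·Cmin/4, Cmin}, rounded half away
from zero, floored at 1, deduplicated. The training data is split into
three equal parts (stratified, seeded) — two for fitting, one for
validation; each candidate k is scored, the top f features feed an
RBF-SVM, and the candidate with the best validation accuracy wins, ties
toward the smaller size. The split does not rotate by default (a 3-fold
rotation option exists, `inner_rotation`). If a class has fewer than 3
training samples the inner split falls back to an unstratified seeded
split.

The benchmark harness runs stratified 10-fold cross-validation (seeded
shuffle; unstratified with a warning when the smallest class has fewer
samples than folds). Per fold, the component size is selected on the
training split only, using the largest feature count of the grid (one size
per fold; the coupling between the size search and the feature-count grid
is an open choice — a single per-fold search keeps the report one-size-
per-fold and costs 5 candidate evaluations instead of 50). Features are
then scored and ranked on the training split, and an SVM trained on the
top f features is evaluated on the held-out fold for every f in the grid
(default 5, 10, ..., 50). SVM hyperparameters are fixed at C = 1,
gamma = "scale" for reproducibility and exposed in `SelectionConfig`.
Everything is deterministic given the seed; a test asserts byte-identical
reports across reruns.

## Simulations

**Entropy ↔ reconstruction error.** Per repetition an n × p matrix of iid
standard normals is drawn (default n = 500, p = 100); the entropy
surrogate H = p/2 + (p/2)·ln 2π + ln|Σ̂| is computed from the sample
covariance via a Cholesky log-determinant, and the total squared
reconstruction error of a 1-component PCA is recorded; after 1000
repetitions the squared Pearson correlation between the two vectors is
reported. Note the ln|Σ̂| term enters with unit weight in this surrogate
(the conventional Gaussian differential entropy carries ½·ln|Σ|); since
Pearson correlation is affine-invariant the discrepancy cannot affect the
R², so the surrogate is kept in this form rather than silently corrected.
Under the iid default the spread of both quantities is pure sampling
variability of the empirical covariance; this yields R² ≈ 0.89 at the
default configuration, compatible with the reference value 0.94 whose
exact generator (e.g. whether the population covariance itself was
randomized) is not known. A Wishart-style mode (`cov_mode="wishart"`)
draws a random population covariance per repetition instead.

**Applicability (two features, two classes, 500 samples).** The
"separated" fixture draws the classes from Gaussians with means (0,0) and
(8,8) and covariances 2·[[1, ±0.95], [±0.95, 1]] — elongated clouds with
opposing trends, centroids ≈ 5.7 within-class SDs apart. The "overlapping"
fixture uses a common covariance [[1, 0.9], [0.9, 1]] and a 0.05-SD
centroid offset. With k = 1 linear PCA and summed raw errors the separated
scores are ≈ 430–475 per feature and the overlapping ones below 1; the
contract checked is the ratio (≥ 50× between the smallest separated and
largest overlapping score), not the absolute values, which depend on the
cloud geometry.

**Recovery fixture.** `generate_informative` plants m features whose class
means are `shift` within-class SDs apart among pure-noise features, labels
balanced. It emulates the mean-shift component of differential expression
only — no correlation structure between features, no heavy tails, no
class-imbalance, no batch effects — so passing recovery tests demonstrate
ranking behavior under clean mean-shift signal, not performance on real
expression data.

## Problem sizes in the tests

The recovery benchmark uses m = 10 shifted features (5 SD) among 200 noise
features at n = 300 over 20 seeds (mean top-10 recall ≥ 0.9); the null
counterpart uses 210 exchangeable features. The CV-protocol checks run on
60-sample, 60-feature datasets with the full 5..50 feature grid, which
exercises every code path of the published protocol at a size where the
whole suite stays interactive.

## Known limitations

- With very few features (p ≲ 20) and k = 1, a single high-variance noise
  feature can dominate a class-wise embedding and outrank weakly shifted
  informative features; the score is designed for the many-feature filter
  regime (hundreds to tens of thousands of features), and the recovery
  guarantees in the tests are stated for that regime.
- The kernel pre-image is a linear approximation; kernel-backend scores
  are noisier rankers than the linear backend on mean-shift signal (the
  corresponding tests assert top-5 containment rather than exact top-3
  ordering).
- Scores carry no significance calibration; the method ranks, it does not
  test. Multiple-testing control is out of scope.
- An autoencoder backend is deliberately not provided (unstable results
  at these sample sizes); the embedding interface accepts only the three
  deterministic backends.
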