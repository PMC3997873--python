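# Methods

`dermamiml` annotates skin-biopsy images with a set of standard
dermatopathology terms. An image is decomposed into visually disjoint
regions, each region is summarized by a texture + structure descriptor, and
a sparse Bayesian multi-instance multi-label (MIML) ensemble maps the
resulting *bag* of region descriptors to per-term annotation probabilities.
This note records the model, the defaults and why, the numerical choices,
and what the synthetic benchmark does and does not demonstrate.

## Image representation

**Segmentation.** Images are rescaled to 800 x 600 and partitioned by
recursive two-way normalized cuts (Shi–Malik): pixel affinities
`W[i,j] = exp(-||c_i - c_j||^2 / s_c^2) * exp(-||p_i - p_j||^2 / s_d^2)`
combine LUV color and spatial position within a 5-pixel radius, each sigma
defaulting to 10% of the corresponding feature range. The second-smallest
generalized eigenvector of `(D - W) x = lambda D x` is thresholded at the
best of 32 evenly spaced candidates (minimum Ncut value; ties to the first
candidate); the largest region is always split next until `k` regions
exist, and any region under `min_pixels` (default 1500) is merged into its
most affine neighbor. Numerical choices that matter:

* The eigenproblem is solved on an integer-factor downsample (at most
  ~160 x 120); labels are upsampled by nearest neighbor and the size
  constraint is enforced at full resolution. This is a runtime choice; the
  procedure is otherwise scale-free.
* The trivial eigenvector `D^{1/2} 1` is removed by a rank-1 deflation
  before the Lanczos iteration. Without it the top eigenvalue is (nearly)
  degenerate whenever the image contains well-separated color blocks and
  the solver can return a vector that does not separate anything. For the
  same reason the start vector is a seeded random draw, never a constant:
  a symmetric start can trap the Krylov space in a symmetry-invariant
  subspace. Everything remains deterministic.
* A disconnected affinity graph is split along its connected components
  first (the zero-cut optimum), and a visually uniform region that resists
  an eigenvector split is bisected along its longer spatial axis. With
  `strict=False` the routine settles for fewer than `k` regions instead of
  raising; the pipeline uses that mode because a synthetic image may simply
  not contain `k` visually distinct areas, and the multi-instance
  assumption is indifferent to the instance count.
* Thresholds leaving either side below the minimum region size are skipped
  during the Ncut search, so speckle-level color modes cannot win.

**Texture descriptor (9 values per region).** `f1..f3` are the mean L, U, V
values over the region's pixels (D65 white point). The region's bounding
box is tiled with 4 x 4 blocks anchored at the bounding-box origin; blocks
containing any non-region (padding) pixel are discarded. `f4..f6` are the
means over valid blocks of the single-level 2-D Haar DWT detail sub-bands
HH, HL, LH of the L channel. The wavelet is a choice — the source material
for this representation names no wavelet — and Haar is the simplest
transform with well-defined detail bands on a 4 x 4 block. `f7..f9`, the
"1st/2nd/3rd order normalized criteria" of the region, are implemented as
the mean, standard deviation and skewness of the region's L values, each
divided by the L range (100); the triple is a replaceable plug-in
(`texture_features.NORMALIZED_CRITERIA`) because the original reference is
not reconstructible.

**Graph descriptor (17 values per region at p = 4).** Region pixels
(black/padding pixels excluded first) are k-means clustered into `p` LUV
color classes (10 restarts, fixed seed — the cited node-seeking heuristic is
not reproducible, k-means is the standard stand-in). Every 8-connected blob
of a class with at least 20 pixels becomes a node at its centroid; a
Delaunay triangulation over the centroids supplies edges weighted by
Euclidean pixel distance (collinear node sets fall back to a path graph).
Features: one average node degree per cluster (`p` values); for every
ordered cluster pair `(a, b)` the mean over cluster-`a` nodes of the
clustering coefficient `ACC_i = 2 C_i / (d_i (d_i - 1))` computed on the
node's cluster-`b` neighbors (`p(p-1)` values; nodes with fewer than two
such neighbors contribute 0); and the weighted diameter of the largest
connected component. The cross-cluster reading of the ACC block is forced
by the 17-value total; `p = 4` is the default that yields 17 features, with
`p` configurable (a five-tissue assumption, `p = 5`, gives 26). Graphs with
under 3 nodes yield all-zero features with a warning rather than an error.

## The MIML learner

Let `s` be the number of terms and `N` the number of training instances
(regions). Latent functions `f_1..f_s` get the joint zero-mean Gaussian
prior `vec(F) ~ N(0, K_term (x) K)` where `K_term` (s x s, unit diagonal)
encodes term–term relationships and `K` is an RBF gram matrix over
standardized region descriptors. For term `i` and bag `j` the bag
activation is the soft max `a_ij = ln((1/n_j) sum_k exp(F_ik))` over the
bag's instances — log-mean-exp, so that a bag of identical instances maps
through unchanged; a plain log-sum-exp mode is available
(`softmax_mode="sum"`). The bag label is Bernoulli through a logistic link
on `a_ij`. The soft max realizes the standard multi-instance assumption
(one strongly positive region suffices) while staying differentiable; the
logistic (rather than probit) link is a choice.

**Laplace approximation.** The posterior mode of `F` is found by damped
Newton iterations (Levenberg-style: the step solves
`(W + C^{-1} + lam I) delta = grad` and `lam` adapts until the objective
does not decrease; the likelihood Hessian of a soft-max/logistic MIML model
is not globally negative definite, so pure Newton can overshoot). Gradients
stop at `tol` (default 1e-6 for single fits, relaxed for ensemble members).
The curvature at the mode provides the Gaussian posterior; a ridge is added
if the curvature is numerically indefinite. All kernel diagonals carry a
1e-6 jitter.

**Prediction.** The Gaussian conditional of a test bag's latents has mean
`F_hat K^{-1} K_*` per term (the Kronecker cross-covariance collapses
because `K_term K_term^{-1} = I`) and per-term covariance
`K_term[ii] (K_** - K_*^T K^{-1} K_*) + V^T Sigma_ii V`. The soft-max
activation is treated by linearization at the predictive mean (delta
method) and the expected sigmoid is integrated with 20-point Gauss–Hermite
quadrature. This replaces an unspecified "EM-like" integration in the
source method with a standard, deterministic approximation.

**Kernel defaults.** Lengthscale: median pairwise instance distance,
randomized log-uniformly within a factor e per ensemble member. Variance:
16 (latent amplitude 4). A unit-variance prior pins bag probabilities well
inside (0, 1) — the logistic link cannot saturate — and underfits even
perfectly separable data; amplitude 4 gives the link a ±4 swing.

## The sparse ensemble

`Q` base learners are generated with randomly sampled term covariances
(`WW^T` of an s x s standard normal, ridge 1e-6, rescaled to unit
diagonal), random lengthscales, and a random 80% bag subsample each
(`max_bags` optionally caps the member size so very large ensembles stay
cheap; the weighting is expected to sort out the resulting weak members).
Sampling replaces any marginal-likelihood optimization of the term
covariance by design.

The combination weights come from a classification relevance vector
machine: rows of the design matrix are (training bag, term) pairs, column
`i` holds learner `i`'s predicted probability, and the binary target is the
true annotation. An ARD prior (per-weight precision `alpha_i`) is updated
by Tipping's rule `alpha_i <- gamma_i / w_i^2`, `gamma_i = 1 - alpha_i
Sigma_ii`, interleaved with a penalized IRLS re-estimation of `w`; weights
whose precision exceeds `alpha_prune` (default 1e12) are pruned. Two
implementation details matter:

* The model carries a bias basis function with its own ARD precision, as in
  Tipping's formulation. Without it, positive-valued probability columns
  are recruited as a surrogate intercept and never prune.
* Iteration stops only when both the weights and the log-precisions have
  settled. Weights alone drift very slowly while precisions still climb
  toward the pruning threshold; stopping on weight change alone freezes the
  ensemble in a half-pruned state.

Surviving weights are clipped at zero (the normalization presumes
non-negativity) and divided by their sum, so the ensemble prediction is a
convex combination of member probabilities and stays in [0, 1]. Each
learner predicts every training bag when the design matrix is built; for a
member's own 80% subsample these values are in-sample. A fully out-of-fold
design would need either a shared stacking holdout (which starves the RVM
at the training sizes used here) or per-member designs (which breaks the
single shared weight vector), so the mild optimism is accepted.

A small utility (`sparse_ensemble.diagnose`) mixes per-term probabilities
into disease probabilities through a user-supplied conditional table,
`p(disease | image) ∝ sum_t p(disease | term_t) p(term_t | image)`.

## Evaluation

Per-term accuracy uses the decision rule "annotate iff probability >= 0.5"
(ties go to annotate). Four multilabel losses follow the standard
definitions: hamming loss (mean decision/truth disagreement), one-error
(top-ranked term not true), coverage (0-based worst rank of a true term),
and ranking loss (fraction of (true, false) pairs ranked wrongly). Ranking
ties break toward the smaller term index and count as misordered in the
ranking loss. Bags whose truth set is empty or full are excluded from
one-error, coverage and ranking loss (their denominators are undefined);
hamming loss uses every bag. Train/test splits use seeded iterative
stratification (rarest term first) so each term's occurrence ratio is
preserved; the reference protocol is a 3:7 train:test split.

## Synthetic data

The clinical corpus the method targets (thousands of images, 15 terms with
occurrence frequencies from about 1.8% to 37%) is private, so the package
generates its own data with the same statistical skeleton:

* **Images** are partitions into Voronoi cells of seed points drawn on
  distinct pixel centers (irregular but convex, hence contiguous, regions).
  Each term has a texture: a base color on an evenly spaced hue wheel,
  Gaussian pixel noise (sd 6), and an optional stripe (±15% luminance
  bands) or spot (-30% luminance dots) mask, so both texture and graph
  descriptors carry term signal. Pattern contrasts are deliberately weaker
  than the hue separation between terms: a texture modulates a region, it
  must not split it visually. Regions not assigned a term are painted a
  light-gray background; pure black never occurs inside a region (black is
  the padding convention).
* **Term sets** are sampled independently per term with configurable
  frequencies (defaults: the 15 clinical occurrence ratios); every sampled
  term receives at least one region, spare regions become background or
  repeats, so the image label is exactly the union of region terms.
  No term co-occurrence structure is modeled (none is documented for the
  clinical corpus); frequencies cap at the region count in the rare
  oversampled case.
* **Feature-space bags** place term instances at distance
  `effect_separation` (default 3.0) from a unit-Gaussian background
  cluster; directions are evenly spaced in 2-D and orthonormal when the
  dimension allows, so the separation parameter means what it says.
  Instance counts are uniform on 5–11 by default, matching the k = 11
  regime.

What the generator does **not** emulate: staining variation, microscope
optics, within-term texture diversity, term correlations, multi-image
patients, or any real histologic morphology. Passing the synthetic
benchmark therefore demonstrates the machinery — segmentation honoring size
constraints, descriptors with the documented layout, calibrated MIML
probabilities, ARD pruning — not clinical accuracy.

## Benchmark problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
full pipeline exercises every code path: one 800 x 600 segmentation at
k = 11 / 1500 px; the pruning experiment with Q = 200 members (each capped
at 12 bags, 10 Newton iterations) on 150 five-term bags at separation 3.0
across train ratios 0.3/0.5/0.7; and end-to-end recovery on 100 images of
120 x 90 with four regions and five equifrequent terms, segmented at k = 7
(deliberate over-segmentation: fragments of one tissue are benign extra
instances, mixed regions are harmful), trained with Q = 50 on the 30%
split. End-to-end quality is summarized as the macro-average of per-term
accuracies on the held-out 70%.

## Known limitations

* Laplace state is dense: fitting cost grows as `O((sN)^3)` per Newton
  step, so members should stay small (the `max_bags` cap); no sparse or
  inducing-point approximation is provided.
* The delta-method/Gauss–Hermite predictive is a linearization; for bags
  with strongly multimodal instance activations it can understate
  uncertainty.
* On near-separable designs the RVM's surviving weights grow slowly
  (logistic separation); the iteration cap, not the tolerance, ends those
  runs.
* Normalized cut cannot split two adjacent regions with identical texture —
  by design it finds *visually* disjoint regions; the spatial-bisection
  fallback only fires when a region is internally uniform.
* The "normalized criteria" texture triple and the cross-cluster ACC
  reading are reconstructions of underspecified descriptors; both are
  isolated behind replaceable functions.
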