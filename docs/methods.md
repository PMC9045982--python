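# Methods

## The co-occurrence model

For a 2D image quantized to gray levels {1..N}, the triple-pixel
co-occurrence tensor counts collinear triples (p, p + o, p + 2o): the
reference pixel, its neighbor at offset o, and the next pixel along the
same direction. Offsets realize the eight 45° directions at Chebyshev
distance d (default d = 1); the row axis points down, so 90° is (−d, 0).
The construction is: count triples over the four canonical directions
{0°, 45°, 90°, 135°}, symmetrize by adding the index-reversed transpose
(S[i,j,k] = t[i,j,k] + t[k,j,i]), then either normalize to a probability
mass function p or rescale to P̄ = N³ · p.

Two choices here were genuinely open:

* **Collinearity.** The distance/direction constraints on the three pixels
  admit, in principle, non-collinear solutions; every worked construction
  step, however, uses a single offset applied twice. We count only
  collinear triples.
* **Direction handling.** Counting the four canonical directions and then
  symmetrizing is exactly equivalent to counting all eight directions raw
  (reversing a triple equals walking it from the other end); counting
  eight *and* symmetrizing would double-count. The test suite proves the
  equivalence by exhaustive comparison on random images. One pooled tensor
  is built across directions, since one feature set is computed per image.

Tensors are stored in coordinate (COO) form — sorted linear cell codes
plus values — so the N = 256 case costs memory proportional to the number
of distinct observed triples (≲ number of pixels × directions), not N³.
Every statistic is a sum weighted by the cell value, so absent cells
contribute nothing and the sparse evaluation is exact.

## The two feature variants

From the normalized tensor p the six original statistics use level-unit
indices (Q = N):

| feature | expression |
|---|---|
| max probability | max pᵢⱼₖ |
| entropy | −Σ pᵢⱼₖ log₂ pᵢⱼₖ |
| energy | Σ p²ᵢⱼₖ |
| correlation | Σ pᵢⱼₖ (i−μx)(j−μy)(k−μz) / (σxσyσz) |
| contrast | Σ pᵢⱼₖ [(i−j)² + (i−k)² + (j−k)²] |
| homogeneity | Σ pᵢⱼₖ / (1 + (i−j)² + (i−k)² + (j−k)²) |

The invariant statistics treat P̄ = N³p as a density sampled at
(i/N, j/N, k/N) ∈ (0, 1]³ and rewrite each statistic as a Riemann sum with
weights Δ = 1/N, Δᵢⱼₖ = 1/N³; marginal moments use P̄x(i) = Σⱼₖ P̄ Δⱼₖ,
μ̄x = Σᵢ (i/N) P̄x(i) Δ, so that μ̄ = μ/N and σ̄ = σ/N exactly. As N → ∞
each Riemann sum converges to an integral of the underlying density, which
is what makes the features asymptotically invariant to quantization.

Numerical conventions:

* 0 · log 0 := 0; logarithms are base 2 throughout. Invariant entropy
  approximates a *differential* entropy and may be negative.
* Degenerate correlation (any marginal σ = 0, e.g. constant images)
  returns 0 with a flag instead of NaN, keeping vectors usable by the
  classifier.
* Homogeneity is the inverse-difference form (squared-difference sum in
  the denominator) in both variants; the source table that lists the
  original features prints contrast and homogeneity identically, an
  evident duplication, and the inverse-difference reading mirrors the
  invariant table.
* Invariant correlation carries the Δᵢⱼₖ weight like its siblings (the
  printed expression omits it); with the weight, invariant correlation
  equals original correlation exactly.

Five identities link the variants on *any* tensor and serve as the
module's primary oracle: entropy_inv = entropy_orig − 3 log₂ N,
energy_inv = N³ energy_orig, maxprob_inv = N³ maxprob_orig,
contrast_inv = contrast_orig / N², correlation_inv = correlation_orig.
Tests assert them to 1e−9 on random tensors.

## Preprocessing

RGB is collapsed with BT.601 luma weights (0.2989, 0.5870, 0.1140),
rounding half away from zero — the behavior of the classic `rgb2gray`.
Enhancement is contrast-limited adaptive histogram equalization; the
method's parameters are not fixed by the source procedure, so defaults
are clip limit 0.01 with an 8 × 8 tile grid, both exposed. Quantization
maps [lo, hi] onto 1-based levels via
level(v) = min(N, ⌊(v − lo)/(hi − lo + 1) · N⌋ + 1); lo/hi default to the
dataset-wide (global) min–max so that all images of a dataset share one
intensity scale, with 0/255 as the fallback when no dataset context
exists. Levels are 1-based so the invariant coordinate i/N is nonzero.

## Classification and evaluation

Training computes the arithmetic mean feature vector per class; a query is
assigned to the nearest centroid in Euclidean distance, ties broken by
class order. Distances are applied to raw features by default (a z-scoring
flag exists because the original features span several orders of
magnitude, but it is off: the identification rule is distance on the raw
statistics). Cross-validation uses seeded *stratified* k-fold splits
(k = 5 → the 80/20 pattern); stratification is our choice — it keeps every
class present in each training split — and the per-fold held-out
predictions are pooled into one confusion matrix. Metrics are one-vs-rest
accuracy/precision/recall per class, macro-averaged (unweighted mean) and
reported in percent to 2 decimals; zero-denominator precision/recall is
defined as 0. The original-vs-invariant comparison is summarized per
metric as the mean over gray levels of 100 × (inv − orig)/orig.

## Synthetic data

The fixture generators target statistical regimes, not imagery:

* `constant`, `checkerboard`, `gradient` — closed-form and boundary cases;
* `smooth_field` — Gaussian white noise smoothed with a wrap-around
  Gaussian filter (correlation length in pixels, default 3.0), rescaled to
  [0, 255]. Its gray-level triple distribution approaches a smooth density,
  the regime in which the invariance argument applies;
* `mixture` — smooth field plus independent speckle, for intermediate
  roughness.

Default image size is 64 × 64 and the two-class study uses 25 images per
class: large enough for stable 5-fold estimates, small enough that the
full 5-level × 2-method sweep runs in about a second on one CPU. Class
separation in the separable preset comes from correlation length (6.0 vs
1.5 pixels — coarse vs fine texture). Per-image seeds are spawned from the
dataset seed, so a dataset is fully determined by its spec and seed.

What passing these tests shows — and does not. The synthetic fields have
stationary statistics, no segmentation noise, no occlusions, and exact
class definitions; results on them validate the *mechanics* (counting,
identities, convergence, classifier plumbing), not clinical performance on
iris, MRI or X-ray data, which depends on acquisition effects the
generators deliberately do not model.

## The invariance experiment

For each replicate, one smooth field is quantized at N ∈ {32, 64, 128} and
both feature variants are extracted. Dispersion across N is measured by
the relative spread (max − min)/mean(|values|), a scale-free measure
chosen because the two variants live on very different scales (original
energy ~ N⁻³, invariant energy ~ 1), making absolute ranges incomparable.
The experiment counts the fraction of 50 seeded replicates in which the
invariant statistic's relative spread is smaller than its original
counterpart's, for entropy, energy and max probability.

At 64 × 64 pixels the N = 128 tensor is sparse (≈ 16k triples in 2M
cells), so the invariant statistics have not fully converged in absolute
terms — sparsity at high N is a known failure mode of the method on small
image areas; the relative-spread comparison against the originals is
nevertheless decisive.

## Known limitations

* No iris localization/segmentation or mask handling; images are used
  whole.
* Only the six statistics above, not the remaining classical Haralick set.
* "3D" refers to gray-value triples on 2D images; volumetric (voxel-stack)
  co-occurrence is out of scope.
* The sweep recomputes features per level from scratch; no caching across
  methods (both variants share the tensor construction cost only within
  `extract_features` calls).
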