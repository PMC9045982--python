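# glcm3d — quantization-invariant triple-pixel co-occurrence texture features

`glcm3d` implements texture identification based on the *triple-pixel*
gray-level co-occurrence matrix (3D-GLCM): an N × N × N tally of how often
gray-level triples (reference pixel, first neighbor, second neighbor) occur
along a line at Chebyshev distance *d* on a 2D image. From this tensor it
computes six Haralick-style statistics — max probability, entropy, energy,
correlation, contrast, homogeneity — in two forms:

* **original**: from the normalized tensor *p*, with indices in level units
  1..N, e.g. entropy −Σ pᵢⱼₖ log₂ pᵢⱼₖ;
* **invariant**: from the rescaled tensor **P̄ = N³ · p**, read as a
  discretized probability density on (0, 1]³ sampled at (i/N, j/N, k/N),
  every statistic written as a Riemann sum with weight Δᵢⱼₖ = 1/N³, e.g.
  entropy −Σ p̄ᵢⱼₖ log₂(p̄ᵢⱼₖ) Δᵢⱼₖ.

For images whose triple distribution approaches a smooth density, the
invariant statistics converge as the number of quantization gray levels N
grows, while the original statistics drift with N (e.g. original entropy
shifts by exactly 3 log₂ N). This matters wherever images are compared
across acquisition or quantization settings — the motivating application is
identification of medical images (iris photographs, brain MRI, chest
X-rays) where the same tissue texture must yield comparable features at 16
through 256 gray levels.

Around the feature extractor the package provides the full comparison
pipeline: grayscale conversion (BT.601 luma), contrast-limited adaptive
histogram equalization, global min–max quantization to N ∈ {16, 32, 64,
128, 256} levels, per-class mean-feature-vector (nearest-centroid)
identification by Euclidean distance, stratified 5-fold cross-validation,
and macro-averaged accuracy/precision/recall reports per gray level and
method, summarized as the mean relative percent increase of the invariant
method over the original.

## Worked example

```python
import numpy as np
from glcm3d import quantize, extract_features
from glcm3d.fixtures import separable_presets, make_two_class_images
from glcm3d.evaluation import sweep_gray_levels, compare_methods

spec_a, spec_b = separable_presets()          # coarse vs fine random fields
images = make_two_class_images(25, spec_a, spec_b, seed=0)

q = quantize(images[0][2], 32)                # 32 gray levels
print(extract_features(q, "original").as_array())
# [2.8200e-02 8.0223e+00 6.3000e-03 5.7510e-01 5.2285e+00 3.8870e-01]
print(extract_features(q, "invariant").as_array())
# [ 9.228059e+02 -6.977700e+00  2.058749e+02  5.751000e-01  5.100000e-03  9.950000e-01]

table = sweep_gray_levels(images, levels=(16, 64, 256), k=5, seed=0)
print(table.to_string(index=False))
#  gray_levels    method  accuracy  precision  recall
#           16  original     100.0     100.00   100.0
#           16 invariant      94.0      94.64    94.0
#           64  original     100.0     100.00   100.0
#           64 invariant      94.0      94.64    94.0
#          256  original     100.0     100.00   100.0
#          256 invariant      86.0      89.06    86.0
```

The feature arrays are in the fixed order (max probability, entropy,
energy, correlation, contrast, homogeneity). Note how the two variants
relate: invariant entropy = original entropy − 3 log₂ 32 = 8.02 − 15 ≈
−6.98, invariant energy = 32³ × original energy, and correlation is
identical (0.5751) — these identities hold exactly for any tensor. The
sweep table has the layout of a per-dataset results table: one row per
(gray level, method) with macro metrics in percent. On this synthetic
two-texture dataset both methods separate the classes well; the invariant
method's advantage appears when features must be compared *across*
quantization levels, which the plain within-level CV does not require.

## Command line

```bash
glcm3d fixtures --preset two-class --n-per-class 25 --out data/
glcm3d extract  --input data/ --levels 16,32,64,128,256 --variant invariant --out feats.csv
glcm3d evaluate --input data/ --k 5 --seed 0 --out report.json
glcm3d compare  --report-a original.json --report-b invariant.json --out summary.csv
```

`extract`/`evaluate` accept any image folder organized one directory per
class (PNG/JPEG/TIFF), so the published experiments can be reproduced by
pointing them at the public datasets; none of the tests require downloads.

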