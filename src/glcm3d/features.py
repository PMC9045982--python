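"""Haralick-style texture statistics from triple co-occurrence tensors.

Two variants of the same six statistics — max probability, entropy, energy,
correlation, contrast, homogeneity — are computed:

* the *original* variant from the normalized tensor p, with cell indices in
  level units 1..Q;
* the *invariant* variant from the rescaled tensor P-bar = N^3 * p, with
  indices mapped to (0, 1] via i/N and every sum carrying the Riemann
  weight Delta_ijk = 1/N^3.

Reading P-bar as a discretized probability density makes the invariant
statistics converge as the number of gray levels N grows (for images whose
triple distribution approaches a smooth density), whereas the original
statistics drift with N.  The two variants are linked by exact identities on
any tensor:

    entropy_inv     = entropy_orig - 3 log2 N
    energy_inv      = N^3 * energy_orig
    max_prob_inv    = N^3 * max_prob_orig
    contrast_inv    = contrast_orig / N^2
    correlation_inv = correlation_orig

which the test suite uses as its primary oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glcm3d.cooccurrence import (
    CANONICAL_ANGLES,
    CooccurrenceTensor,
    ScaledTensor,
    count_triples,
    normalize,
    scale_invariant,
    symmetrize,
)
from glcm3d.errors import DegenerateInputError, InvalidInputError, InvalidStateError
from glcm3d.preprocessing import QuantizedImage

#: Fixed feature order used in vectors and CSV columns.
FEATURE_NAMES = (
    "max_probability",
    "entropy",
    "energy",
    "correlation",
    "contrast",
    "homogeneity",
)

VARIANTS = ("original", "invariant")


@dataclass(frozen=True)
class MarginalStats:
    """Index-marginal means and standard deviations of a tensor.

    ``scaled=False``: level units (means in [1, N]).
    ``scaled=True``: normalized units i/N in (0, 1]; then mu_scaled = mu/N
    and sigma_scaled = sigma/N exactly.
    """

    mu_x: float
    mu_y: float
    mu_z: float
    sigma_x: float
    sigma_y: float
    sigma_z: float
    scaled: bool


@dataclass(frozen=True)
class FeatureVector:
    """The six texture statistics in fixed order, plus provenance.

    ``degenerate_correlation`` marks tensors where a marginal standard
    deviation vanished (e.g. constant images); correlation is then reported
    as 0 rather than NaN so vectors stay usable downstream.
    """

    max_probability: float
    entropy: float
    energy: float
    correlation: float
    contrast: float
    homogeneity: float
    variant: str
    n_levels: int
    degenerate_correlation: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) for name in FEATURE_NAMES], dtype=np.float64
        )

    @classmethod
    def from_array(
        cls, arr: np.ndarray, variant: str, n_levels: int
    ) -> "FeatureVector":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != (len(FEATURE_NAMES),):
            raise InvalidInputError(
                f"expected {len(FEATURE_NAMES)} features, got shape {arr.shape}"
            )
        return cls(*arr.tolist(), variant=variant, n_levels=n_levels)


def _marginal_moments(idx, weights):
    """Mean/std of one index under cell weights (level units)."""
    mu = float(np.sum(idx * weights))
    var = float(np.sum((idx - mu) ** 2 * weights))
    return mu, float(np.sqrt(max(var, 0.0)))


def marginals(tensor: CooccurrenceTensor | ScaledTensor) -> MarginalStats:
    """Marginal means/standard deviations over the three tensor axes.

    For a normalized tensor the moments are in level units (mu_x = sum of
    i * p_x(i) with p_x(i) = sum over j,k of p(i,j,k)).  For a scaled tensor
    the marginal density P-bar_x(i) = sum over j,k of P-bar * Delta_jk is
    integrated against the coordinate i/N with weight Delta = 1/N, which
    gives exactly the level-unit moments divided by N.
    """
    if isinstance(tensor, ScaledTensor):
        n = tensor.n_levels
        # Work in level units on p = P-bar / N^3, then rescale by 1/N.
        p = tensor.vals / n**3
        i, j, k = tensor.indices()
        scaled = True
    elif isinstance(tensor, CooccurrenceTensor):
        if not tensor.normalized:
            raise InvalidStateError("marginals expects a normalized tensor")
        n = tensor.n_levels
        p = tensor.vals
        i, j, k = tensor.indices()
        scaled = False
    else:
        raise InvalidInputError(f"unsupported tensor type {type(tensor)!r}")
    mx, sx = _marginal_moments(i, p)
    my, sy = _marginal_moments(j, p)
    mz, sz = _marginal_moments(k, p)
    if scaled:
        mx, my, mz, sx, sy, sz = (v / n for v in (mx, my, mz, sx, sy, sz))
    return MarginalStats(mx, my, mz, sx, sy, sz, scaled=scaled)


def original_features(p: CooccurrenceTensor) -> FeatureVector:
    """The six statistics of the normalized tensor, in level units.

    entropy uses log base 2 with 0*log 0 := 0; homogeneity is the inverse
    difference moment 1 / (1 + sum of pairwise squared index differences);
    correlation is 0 (flagged) when any marginal standard deviation is zero.

    Raises
    ------
    InvalidStateError
        If the tensor is not normalized.
    DegenerateInputError
        If the tensor is empty.
    """
    if not p.normalized:
        raise InvalidStateError("original_features expects a normalized tensor")
    if p.vals.size == 0:
        raise DegenerateInputError("cannot compute features of an empty tensor")
    v = p.vals
    i, j, k = p.indices()
    m = marginals(p)
    maxp = float(v.max())
    pos = v > 0
    entropy = float(-np.sum(v[pos] * np.log2(v[pos]))) + 0.0  # avoid -0.0
    energy = float(np.sum(v**2))
    diff2 = (i - j) ** 2 + (i - k) ** 2 + (j - k) ** 2
    contrast = float(np.sum(v * diff2))
    homogeneity = float(np.sum(v / (1.0 + diff2)))
    degenerate = min(m.sigma_x, m.sigma_y, m.sigma_z) == 0.0
    if degenerate:
        corr = 0.0
    else:
        corr = float(
            np.sum(v * (i - m.mu_x) * (j - m.mu_y) * (k - m.mu_z))
            / (m.sigma_x * m.sigma_y * m.sigma_z)
        )
    return FeatureVector(
        maxp, entropy, energy, corr, contrast, homogeneity,
        variant="original", n_levels=p.n_levels,
        degenerate_correlation=degenerate,
    )


def invariant_features(pbar: ScaledTensor) -> FeatureVector:
    """The six statistics of the scaled tensor P-bar, as Riemann sums.

    Indices enter through the normalized coordinates i/N in (0, 1] and every
    sum carries Delta_ijk = 1/N^3, so each statistic approximates an
    integral against the underlying triple density; entropy may be negative
    (it approximates a differential entropy).  Correlation carries Delta_ijk
    like its siblings, making it identical to the original correlation.
    """
    if not isinstance(pbar, ScaledTensor):
        raise InvalidInputError("invariant_features expects a ScaledTensor")
    if pbar.vals.size == 0:
        raise DegenerateInputError("cannot compute features of an empty tensor")
    n = pbar.n_levels
    d3 = 1.0 / n**3
    v = pbar.vals
    x, y, z = (idx / n for idx in pbar.indices())
    m = marginals(pbar)
    maxp = float(v.max())
    pos = v > 0
    entropy = float(-np.sum(v[pos] * np.log2(v[pos])) * d3) + 0.0
    energy = float(np.sum(v**2) * d3)
    diff2 = (x - y) ** 2 + (x - z) ** 2 + (y - z) ** 2
    contrast = float(np.sum(v * diff2) * d3)
    homogeneity = float(np.sum(v * d3 / (1.0 + diff2)))
    degenerate = min(m.sigma_x, m.sigma_y, m.sigma_z) == 0.0
    if degenerate:
        corr = 0.0
    else:
        corr = float(
            np.sum(v * d3 * (x - m.mu_x) * (y - m.mu_y) * (z - m.mu_z))
            / (m.sigma_x * m.sigma_y * m.sigma_z)
        )
    return FeatureVector(
        maxp, entropy, energy, corr, contrast, homogeneity,
        variant="invariant", n_levels=n,
        degenerate_correlation=degenerate,
    )


def extract_features(
    q: QuantizedImage,
    variant: str = "original",
    d: int = 1,
    thetas: tuple[int, ...] = CANONICAL_ANGLES,
) -> FeatureVector:
    """Full per-image pipeline: count triples, symmetrize, compute features.

    ``variant='original'`` normalizes the symmetric tensor and evaluates the
    level-unit statistics; ``variant='invariant'`` rescales it to P-bar and
    evaluates the Riemann-sum statistics.
    """
    if variant not in VARIANTS:
        raise InvalidInputError(f"variant must be one of {VARIANTS}")
    t = symmetrize(count_triples(q, d=d, thetas=thetas))
    if t.total() == 0:
        raise DegenerateInputError("image contains no collinear triple")
    if variant == "original":
        return original_features(normalize(t))
    return invariant_features(scale_invariant(t))


def level_dispersion(
    image: np.ndarray,
    levels: tuple[int, ...] = (32, 64, 128),
    feature_names: tuple[str, ...] = ("entropy", "energy", "max_probability"),
    d: int = 1,
    lo: float = 0,
    hi: float = 255,
) -> dict[str, tuple[float, float]]:
    """Across-level dispersion of each feature, original vs invariant.

    Quantizes one gray image at each level count, extracts both feature
    variants, and measures how much each statistic moves across levels using
    the scale-free relative spread (max - min) / mean(|values|).  An
    asymptotically invariant feature has a much smaller relative spread than
    its level-dependent original counterpart.

    Returns
    -------
    dict mapping feature name to (original_spread, invariant_spread).
    """
    from glcm3d.preprocessing import quantize  # local import: avoids cycle

    per_variant: dict[str, dict[str, list[float]]] = {
        "original": {f: [] for f in feature_names},
        "invariant": {f: [] for f in feature_names},
    }
    for n_levels in levels:
        q = quantize(image, n_levels, lo, hi)
        for variant in ("original", "invariant"):
            fv = extract_features(q, variant=variant, d=d)
            for f in feature_names:
                per_variant[variant][f].append(getattr(fv, f))

    def rel_spread(values: list[float]) -> float:
        arr = np.asarray(values)
        denom = float(np.mean(np.abs(arr)))
        if denom == 0:
            return 0.0
        return float((arr.max() - arr.min()) / denom)

    return {
        f: (rel_spread(per_variant["original"][f]), rel_spread(per_variant["invariant"][f]))
        for f in feature_names
    }
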