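"""Grayscale conversion, adaptive histogram equalization and quantization.

The preprocessing chain is convert -> enhance -> quantize: an RGB raster is
collapsed to a single luma channel, contrast-enhanced with contrast-limited
adaptive histogram equalization (CLAHE), and finally mapped onto N discrete
gray levels with a min-max rule.  Levels are 1-based ({1..N}) so that the
normalized coordinate i/N used by the invariant features lies in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

from glcm3d.errors import InvalidInputError

#: ITU-R BT.601 luma weights, the weighting used by MATLAB's rgb2gray.
BT601_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])

#: Gray-level counts examined in the quantization sweep.
STANDARD_LEVELS = (16, 32, 64, 128, 256)

# A GrayImage is a 2D uint8/integer array with values in [0, 255]; we keep it
# as a plain ndarray rather than wrapping it.
GrayImage = np.ndarray


@dataclass(frozen=True)
class QuantizedImage:
    """A gray image mapped onto integer levels {1..N}.

    Attributes
    ----------
    levels : ndarray
        2D integer array, every value in {1..n_levels}.
    n_levels : int
        Number of quantization levels N.
    lo, hi : float
        The min-max bounds used for the mapping.
    """

    levels: np.ndarray
    n_levels: int
    lo: float
    hi: float

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.ndim != 2:
            raise InvalidInputError("levels must be a 2D array")
        if lv.size and (lv.min() < 1 or lv.max() > self.n_levels):
            raise InvalidInputError(
                f"levels must lie in 1..{self.n_levels}, got "
                f"[{lv.min()}, {lv.max()}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.levels.shape


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round rounds half to even; the reference conversion rounds half away
    # from zero (values here are non-negative, so this is floor(x + 0.5)).
    return np.floor(x + 0.5)


def rgb_to_gray(image: np.ndarray) -> GrayImage:
    """Collapse a 3-channel RGB raster to a single luma channel.

    Uses the BT.601 weights (0.2989, 0.5870, 0.1140) with rounding half away
    from zero, matching the classic ``rgb2gray`` conversion.  2D input and
    single-channel 3D input pass through unchanged (as uint8).

    Raises
    ------
    InvalidInputError
        If the input is not 2D or 3D, or has a channel count other than 1 or 3.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=True)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            return arr[:, :, 0].astype(np.uint8, copy=True)
        if arr.shape[2] == 3:
            luma = arr.astype(np.float64) @ BT601_WEIGHTS
            return np.clip(_round_half_away(luma), 0, 255).astype(np.uint8)
        raise InvalidInputError(
            f"expected 1 or 3 channels, got {arr.shape[2]}"
        )
    raise InvalidInputError(f"expected 2D or 3D raster, got ndim={arr.ndim}")


def enhance_ahe(
    g: GrayImage,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
) -> GrayImage:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    Parameters
    ----------
    g : GrayImage
        2D gray image with values in [0, 255].
    clip_limit : float
        Histogram clipping limit in (0, 1]; higher means more contrast.
    tile_grid : (rows, cols)
        Number of contextual tiles along each axis.

    Returns
    -------
    GrayImage with the same shape, values in [0, 255].
    """
    arr = np.asarray(g)
    if arr.ndim != 2:
        raise InvalidInputError("enhance_ahe expects a 2D gray image")
    if not 0 < clip_limit <= 1:
        raise InvalidInputError("clip_limit must be in (0, 1]")
    rows, cols = tile_grid
    if rows < 1 or cols < 1 or rows > arr.shape[0] or cols > arr.shape[1]:
        raise InvalidInputError(
            f"tile grid {tile_grid} does not fit image of shape {arr.shape}"
        )
    if arr.min() == arr.max():
        # Flat histogram: nothing to redistribute.
        return arr.astype(np.uint8, copy=True)
    kernel = (
        max(1, arr.shape[0] // rows),
        max(1, arr.shape[1] // cols),
    )
    out = exposure.equalize_adapthist(
        arr.astype(np.uint8), kernel_size=kernel, clip_limit=clip_limit
    )
    return np.clip(_round_half_away(out * 255.0), 0, 255).astype(np.uint8)


def quantize(
    g: GrayImage, n_levels: int, lo: float = 0, hi: float = 255
) -> QuantizedImage:
    """Map intensities in [lo, hi] onto 1-based gray levels {1..N}.

    The mapping is ``level(v) = min(N, floor((v - lo) / (hi - lo + 1) * N) + 1)``
    after clipping v into [lo, hi].  With lo=0, hi=255, N=256 this is the
    identity up to the +1 level shift.  The bounds are normally the
    dataset-wide (global) min and max so that all images of a dataset share
    one intensity scale.

    Raises
    ------
    InvalidInputError
        If lo >= hi or N < 2.
    """
    if lo >= hi:
        raise InvalidInputError(f"lo must be < hi, got lo={lo}, hi={hi}")
    if not 2 <= int(n_levels) <= 256:
        raise InvalidInputError(f"n_levels must be in 2..256, got {n_levels}")
    n_levels = int(n_levels)
    arr = np.asarray(g, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidInputError("quantize expects a 2D gray image")
    v = np.clip(arr, lo, hi)
    lev = np.floor((v - lo) / (hi - lo + 1) * n_levels).astype(np.int64) + 1
    lev = np.minimum(lev, n_levels)
    return QuantizedImage(levels=lev, n_levels=n_levels, lo=float(lo), hi=float(hi))


def dataset_bounds(images: list[np.ndarray]) -> tuple[float, float]:
    """Global min-max intensity bounds over a dataset of gray images."""
    if not images:
        raise InvalidInputError("dataset_bounds requires at least one image")
    lo = min(float(np.min(im)) for im in images)
    hi = max(float(np.max(im)) for im in images)
    return lo, hi
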