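"""Deterministic synthetic texture generators.

These generators target the statistical regimes the pipeline cares about
rather than any particular imagery: constant and periodic patterns for
closed-form checks, smooth Gaussian random fields (whose gray-level triple
distribution approaches a smooth density — the regime in which the
invariant features converge), and two-class mixtures with controllable
separation for classifier tests.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from glcm3d.errors import InvalidInputError
from glcm3d.preprocessing import GrayImage

KINDS = ("constant", "checkerboard", "gradient", "smooth_field", "mixture")


@dataclass(frozen=True)
class TextureSpec:
    """Recipe for one deterministic synthetic image.

    Parameters
    ----------
    kind : str
        One of constant, checkerboard, gradient, smooth_field, mixture.
    shape : (rows, cols)
        Image size, at least 3x3.
    value : int
        Gray value for ``constant``; low value for ``checkerboard``.
    period : int
        Tile size for ``checkerboard``.
    correlation_length : float
        Gaussian smoothing radius (pixels) for ``smooth_field`` — larger
        means coarser texture.
    offset : float
        Additive gray-level shift for ``mixture`` class separation.
    seed : int
        Seed for the random kinds; identical spec implies identical image.
    """

    kind: str
    shape: tuple[int, int] = (64, 64)
    value: int = 128
    period: int = 4
    correlation_length: float = 3.0
    offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InvalidInputError(f"kind must be one of {KINDS}")
        if self.shape[0] < 3 or self.shape[1] < 3:
            raise InvalidInputError("shape must be at least 3x3")
        if self.kind == "checkerboard" and self.period < 1:
            raise InvalidInputError("period must be >= 1")
        if self.kind == "smooth_field" and self.correlation_length <= 0:
            raise InvalidInputError("correlation_length must be positive")


def _smooth_field(shape, correlation_length, rng) -> np.ndarray:
    noise = rng.standard_normal(shape)
    field_arr = ndimage.gaussian_filter(noise, sigma=correlation_length, mode="wrap")
    lo, hi = field_arr.min(), field_arr.max()
    if hi == lo:  # vanishing variance after smoothing; fall back to flat
        return np.full(shape, 128.0)
    return (field_arr - lo) / (hi - lo) * 255.0


def make_image(spec: TextureSpec) -> GrayImage:
    """Render a spec into a gray image (uint8, values in [0, 255])."""
    rows, cols = spec.shape
    if spec.kind == "constant":
        img = np.full(spec.shape, float(np.clip(spec.value, 0, 255)))
    elif spec.kind == "checkerboard":
        r, c = np.indices(spec.shape)
        tile = ((r // spec.period) + (c // spec.period)) % 2
        lo = float(np.clip(spec.value, 0, 255))
        img = np.where(tile == 0, lo, 255.0 - lo)
    elif spec.kind == "gradient":
        img = np.tile(np.linspace(0, 255, cols), (rows, 1))
    elif spec.kind == "smooth_field":
        rng = np.random.default_rng(spec.seed)
        img = _smooth_field(spec.shape, spec.correlation_length, rng)
        img = np.clip(img + spec.offset, 0, 255)
    else:  # mixture: smooth field + independent fine-grained speckle
        rng = np.random.default_rng(spec.seed)
        base = _smooth_field(spec.shape, spec.correlation_length, rng)
        speckle = rng.standard_normal(spec.shape) * 20.0
        img = np.clip(base + speckle + spec.offset, 0, 255)
    return np.floor(img + 0.5).astype(np.uint8)


def _vary_seed(spec: TextureSpec, seed: int) -> TextureSpec:
    return TextureSpec(
        kind=spec.kind, shape=spec.shape, value=spec.value, period=spec.period,
        correlation_length=spec.correlation_length, offset=spec.offset,
        seed=seed,
    )


def make_two_class_images(
    n_per_class: int, spec_a: TextureSpec, spec_b: TextureSpec, seed: int = 0
) -> list[tuple[str, str, GrayImage]]:
    """In-memory two-class dataset: ``(id, label, image)`` records.

    Each image gets its own sub-seed derived from ``seed``, so the dataset
    is fully determined by (n_per_class, spec_a, spec_b, seed).
    """
    if n_per_class < 1:
        raise InvalidInputError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2 * n_per_class)]
    records = []
    for idx in range(n_per_class):
        records.append(
            (
                f"a_{idx:03d}",
                "class_a",
                make_image(_vary_seed(spec_a, child_seeds[idx])),
            )
        )
    for idx in range(n_per_class):
        records.append(
            (
                f"b_{idx:03d}",
                "class_b",
                make_image(_vary_seed(spec_b, child_seeds[n_per_class + idx])),
            )
        )
    return records


def make_two_class_dataset(
    out_dir: str | Path,
    n_per_class: int,
    spec_a: TextureSpec,
    spec_b: TextureSpec,
    seed: int = 0,
) -> Path:
    """Write a two-class image folder (one subdirectory per class) + manifest.

    Produces ``out_dir/class_a/*.png``, ``out_dir/class_b/*.png`` and
    ``out_dir/manifest.csv`` with columns id, path, label, seed.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    records = make_two_class_images(n_per_class, spec_a, spec_b, seed=seed)
    rows = []
    for img_id, label, img in records:
        cls_dir = out_dir / label
        cls_dir.mkdir(parents=True, exist_ok=True)
        path = cls_dir / f"{img_id}.png"
        iio.imwrite(path, img)
        rows.append(
            {"id": img_id, "path": str(path.relative_to(out_dir)),
             "label": label, "seed": seed}
        )
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "path", "label", "seed"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest


#: Preset pair used by the separability harness: coarse vs fine texture.
def separable_presets(shape=(64, 64)) -> tuple[TextureSpec, TextureSpec]:
    """Well-separated two-class presets (coarse vs fine smooth fields)."""
    return (
        TextureSpec(kind="smooth_field", shape=shape, correlation_length=6.0),
        TextureSpec(kind="smooth_field", shape=shape, correlation_length=1.5),
    )
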