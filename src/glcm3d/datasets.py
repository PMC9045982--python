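"""Loading image folders organized one directory per class."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from glcm3d.errors import InvalidInputError
from glcm3d.preprocessing import GrayImage, enhance_ahe, rgb_to_gray

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


def load_class_folder(
    root: str | Path,
    ahe: bool = True,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
) -> list[tuple[str, str, GrayImage]]:
    """Load a dataset laid out as ``root/<class>/<image>``.

    Every raster is converted to gray and (by default) enhanced with CLAHE.
    Returns ``(id, label, image)`` records sorted by path for determinism.
    """
    root = Path(root)
    if not root.is_dir():
        raise InvalidInputError(f"{root} is not a directory")
    records = []
    for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for img_path in sorted(cls_dir.iterdir()):
            if img_path.suffix.lower() not in IMAGE_SUFFIXES:
                continue
            arr = np.asarray(iio.imread(img_path))
            if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
                arr = arr[:, :, :3]
            g = rgb_to_gray(arr)
            if ahe:
                g = enhance_ahe(g, clip_limit=clip_limit, tile_grid=tile_grid)
            records.append((f"{cls_dir.name}/{img_path.stem}", cls_dir.name, g))
    if not records:
        raise InvalidInputError(f"no images found under {root}")
    return records
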