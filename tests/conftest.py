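"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from glcm3d.cooccurrence import CooccurrenceTensor, direction_offset
from glcm3d.preprocessing import QuantizedImage


def brute_force_triples(levels: np.ndarray, n: int, d: int, thetas) -> np.ndarray:
    """Dense triple-counting oracle: explicit loop over pixels/directions."""
    out = np.zeros((n, n, n))
    rows, cols = levels.shape
    for theta in thetas:
        off = direction_offset(theta, d)
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + off.d_row, c + off.d_col
                r3, c3 = r + 2 * off.d_row, c + 2 * off.d_col
                if 0 <= r2 < rows and 0 <= c2 < cols and 0 <= r3 < rows and 0 <= c3 < cols:
                    out[levels[r, c] - 1, levels[r2, c2] - 1, levels[r3, c3] - 1] += 1
    return out


def random_quantized(rng, max_side: int = 8, max_levels: int = 8) -> QuantizedImage:
    n = int(rng.integers(2, max_levels + 1))
    shape = tuple(rng.integers(3, max_side + 1, 2))
    levels = rng.integers(1, n + 1, shape)
    return QuantizedImage(levels=levels, n_levels=n, lo=0, hi=255)


def random_symmetric_tensor(rng, max_levels: int = 6) -> CooccurrenceTensor:
    """Random non-degenerate symmetric count tensor."""
    n = int(rng.integers(2, max_levels + 1))
    counts = rng.integers(0, 5, (n, n, n)).astype(float)
    counts = counts + counts.transpose(2, 1, 0)
    if counts.sum() == 0:
        counts[0, 0, 0] = counts[-1, -1, -1] = 1.0
    return CooccurrenceTensor.from_dense(counts, symmetric=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
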