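"""Triple-pixel co-occurrence tensors.

The central object is an N x N x N tensor counting collinear gray-level
triples (reference pixel, first neighbor at offset o, second neighbor at
offset 2o) over a set of directions at Chebyshev distance d.  Construction
follows four steps: the N^3 index space is the implicit "frame", triples are
counted, the tensor is symmetrized by adding its index-reversed transpose,
and finally either normalized to a probability mass function or rescaled by
N^3 into the density-like tensor P-bar used by the quantization-invariant
features.

Tensors are stored in coordinate (COO) form — a sorted array of linear cell
codes plus a value array — so that the N = 256 case (16.7M cells dense)
costs only as much as the number of distinct triples actually observed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from glcm3d.errors import DegenerateInputError, InvalidInputError, InvalidStateError
from glcm3d.preprocessing import QuantizedImage

#: The four canonical directions; with symmetrization they are equivalent to
#: counting all eight raw.
CANONICAL_ANGLES = (0, 45, 90, 135)
ALL_ANGLES = (0, 45, 90, 135, 180, 225, 270, 315)

_ANGLE_TO_UNIT = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
    180: (0, -1),
    225: (1, -1),
    270: (1, 0),
    315: (1, 1),
}


@dataclass(frozen=True)
class Offset:
    """A displacement (d_row, d_col) realizing direction theta at distance d.

    Row axis points down the image, column axis points right, so 90 degrees
    (up) is a negative row step.  The Chebyshev norm max(|d_row|, |d_col|)
    equals d.
    """

    d_row: int
    d_col: int
    theta_degrees: int
    distance: int

    def __post_init__(self) -> None:
        if max(abs(self.d_row), abs(self.d_col)) != self.distance:
            raise InvalidInputError(
                "offset Chebyshev norm must equal the distance"
            )


def direction_offset(theta_degrees: int, d: int = 1) -> Offset:
    """Offset vector for one of the eight 45-degree directions.

    Raises
    ------
    InvalidInputError
        For an angle outside {0, 45, ..., 315} or d < 1.
    """
    if theta_degrees not in _ANGLE_TO_UNIT:
        raise InvalidInputError(
            f"theta must be one of {sorted(_ANGLE_TO_UNIT)}, got {theta_degrees}"
        )
    if d < 1:
        raise InvalidInputError(f"distance must be >= 1, got {d}")
    ur, uc = _ANGLE_TO_UNIT[theta_degrees]
    return Offset(ur * d, uc * d, theta_degrees, d)


def _sum_duplicates(codes: np.ndarray, vals: np.ndarray):
    """Collapse duplicate cell codes, summing their values; returns sorted."""
    if codes.size == 0:
        return codes.astype(np.int64), vals.astype(np.float64)
    uniq, inv = np.unique(codes, return_inverse=True)
    summed = np.bincount(inv, weights=vals, minlength=uniq.size)
    return uniq.astype(np.int64), summed.astype(np.float64)


@dataclass(frozen=True)
class CooccurrenceTensor:
    """Sparse N x N x N co-occurrence tensor of gray-level triples.

    ``codes`` holds linear cell indices (i-1)*N^2 + (j-1)*N + (k-1) for
    1-based levels (i, j, k) = (reference, first neighbor, second neighbor),
    sorted and unique; ``vals`` the corresponding counts or probabilities.
    """

    codes: np.ndarray
    vals: np.ndarray
    n_levels: int
    distance: int = 1
    directions: tuple[int, ...] = CANONICAL_ANGLES
    symmetric: bool = False
    normalized: bool = False
    empty: bool = field(default=False)

    def total(self) -> float:
        """Sum of all tensor entries."""
        return float(self.vals.sum()) if self.vals.size else 0.0

    def indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-based (i, j, k) index arrays for the stored cells."""
        n = self.n_levels
        i = self.codes // (n * n) + 1
        j = (self.codes // n) % n + 1
        k = self.codes % n + 1
        return i, j, k

    def value(self, i: int, j: int, k: int) -> float:
        """Entry at 1-based cell (i, j, k); zero if not stored."""
        n = self.n_levels
        code = (i - 1) * n * n + (j - 1) * n + (k - 1)
        pos = np.searchsorted(self.codes, code)
        if pos < self.codes.size and self.codes[pos] == code:
            return float(self.vals[pos])
        return 0.0

    def to_dense(self) -> np.ndarray:
        """Dense (N, N, N) array; intended for small N (tests, export)."""
        n = self.n_levels
        out = np.zeros(n * n * n)
        out[self.codes] = self.vals
        return out.reshape(n, n, n)

    @classmethod
    def from_dense(
        cls, arr: np.ndarray, *, distance: int = 1,
        directions: tuple[int, ...] = CANONICAL_ANGLES,
        symmetric: bool = False, normalized: bool = False,
    ) -> "CooccurrenceTensor":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 3 or len(set(arr.shape)) != 1:
            raise InvalidInputError("expected a cubic 3D array")
        flat = arr.ravel()
        codes = np.flatnonzero(flat)
        return cls(
            codes=codes.astype(np.int64), vals=flat[codes].copy(),
            n_levels=arr.shape[0], distance=distance, directions=directions,
            symmetric=symmetric, normalized=normalized,
            empty=codes.size == 0,
        )


def count_triples(
    q: QuantizedImage,
    d: int = 1,
    thetas: tuple[int, ...] = CANONICAL_ANGLES,
) -> CooccurrenceTensor:
    """Count collinear gray-level triples over the given directions.

    For every direction theta with offset o and every pixel p such that
    p + o and p + 2o lie inside the image, the cell
    (I(p), I(p+o), I(p+2o)) is incremented.  Counts from all directions
    accumulate into one tensor.  An image too small to contain any triple
    yields an all-zero tensor with the ``empty`` flag set (not an error).
    """
    levels = np.asarray(q.levels, dtype=np.int64)
    n = q.n_levels
    rows, cols = levels.shape
    all_codes = []
    for theta in thetas:
        off = direction_offset(theta, d)
        dr, dc = off.d_row, off.d_col
        r0, r1 = max(0, -2 * dr), rows - max(0, 2 * dr)
        c0, c1 = max(0, -2 * dc), cols - max(0, 2 * dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = levels[r0:r1, c0:c1]
        b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        c = levels[r0 + 2 * dr:r1 + 2 * dr, c0 + 2 * dc:c1 + 2 * dc]
        codes = ((a - 1) * n * n + (b - 1) * n + (c - 1)).ravel()
        all_codes.append(codes)
    if not all_codes:
        return CooccurrenceTensor(
            codes=np.empty(0, dtype=np.int64), vals=np.empty(0),
            n_levels=n, distance=d, directions=tuple(thetas), empty=True,
        )
    codes = np.concatenate(all_codes)
    uniq, counts = np.unique(codes, return_counts=True)
    return CooccurrenceTensor(
        codes=uniq.astype(np.int64), vals=counts.astype(np.float64),
        n_levels=n, distance=d, directions=tuple(thetas),
        empty=uniq.size == 0,
    )


def symmetrize(t: CooccurrenceTensor) -> CooccurrenceTensor:
    """Add the index-reversed transpose: S[i,j,k] = t[i,j,k] + t[k,j,i].

    The total doubles; afterwards S[i,j,k] == S[k,j,i] for every cell.
    Symmetrizing the 4 canonical directions is equivalent to counting all 8
    directions raw, since reversing a triple is the same as walking it from
    the opposite end.

    Raises
    ------
    InvalidStateError
        If the tensor is already symmetric (would double count).
    """
    if t.symmetric:
        raise InvalidStateError("tensor is already symmetric")
    n = t.n_levels
    i, j, k = t.indices()
    rev = (k - 1) * n * n + (j - 1) * n + (i - 1)
    codes = np.concatenate([t.codes, rev])
    vals = np.concatenate([t.vals, t.vals])
    codes, vals = _sum_duplicates(codes, vals)
    return replace(t, codes=codes, vals=vals, symmetric=True)


def normalize(t: CooccurrenceTensor) -> CooccurrenceTensor:
    """Divide every entry by the tensor total so the result sums to 1.

    Raises
    ------
    DegenerateInputError
        If the tensor total is zero.
    """
    s = t.total()
    if s <= 0:
        raise DegenerateInputError("cannot normalize an all-zero tensor")
    return replace(t, vals=t.vals / s, normalized=True)


@dataclass(frozen=True)
class ScaledTensor:
    """The density-like tensor P-bar = N^3 * p (COO form).

    Dividing raw counts by total * Delta_ijk with Delta_ijk = 1/N^3 turns the
    co-occurrence distribution into a Riemann-sum approximation of a
    probability density on the unit cube, evaluated at grid points
    (i/N, j/N, k/N); its entries satisfy sum(P-bar) * Delta_ijk = 1.
    """

    codes: np.ndarray
    vals: np.ndarray
    n_levels: int

    def total_mass(self) -> float:
        """Sum of P-bar * Delta_ijk; equals 1 for a valid tensor."""
        return float(self.vals.sum()) / self.n_levels**3

    def indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = self.n_levels
        i = self.codes // (n * n) + 1
        j = (self.codes // n) % n + 1
        k = self.codes % n + 1
        return i, j, k

    def to_dense(self) -> np.ndarray:
        n = self.n_levels
        out = np.zeros(n * n * n)
        out[self.codes] = self.vals
        return out.reshape(n, n, n)


def scale_invariant(t: CooccurrenceTensor) -> ScaledTensor:
    """Rescale a symmetric count tensor into P-bar = counts / (total * Delta_ijk).

    Equivalently P-bar = N^3 * p where p is the normalized tensor.

    Raises
    ------
    InvalidStateError
        If the tensor is not symmetric or was already normalized.
    DegenerateInputError
        If the total is zero.
    """
    if not t.symmetric:
        raise InvalidStateError("scale_invariant expects a symmetrized tensor")
    if t.normalized:
        raise InvalidStateError("scale_invariant expects raw (un-normalized) counts")
    s = t.total()
    if s <= 0:
        raise DegenerateInputError("cannot scale an all-zero tensor")
    n3 = t.n_levels**3
    return ScaledTensor(
        codes=t.codes.copy(), vals=t.vals * (n3 / s), n_levels=t.n_levels
    )


def save_tensor(t: CooccurrenceTensor, csv_path: str | Path) -> None:
    """Write a tensor as coordinate-list CSV (i,j,k,count) + JSON sidecar."""
    csv_path = Path(csv_path)
    i, j, k = t.indices()
    with open(csv_path, "w") as fh:
        fh.write("i,j,k,count\n")
        for ii, jj, kk, v in zip(i, j, k, t.vals):
            fh.write(f"{ii},{jj},{kk},{v:.17g}\n")
    meta = {
        "n_levels": t.n_levels,
        "distance": t.distance,
        "directions": list(t.directions),
        "symmetric": t.symmetric,
        "normalized": t.normalized,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_tensor(csv_path: str | Path) -> CooccurrenceTensor:
    """Read a tensor written by :func:`save_tensor` (bit-exact for counts)."""
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    n = meta["n_levels"]
    rows = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
    if rows.size:
        i, j, k, v = rows.T
        codes = ((i - 1) * n * n + (j - 1) * n + (k - 1)).astype(np.int64)
        order = np.argsort(codes)
        codes, vals = codes[order], v[order].astype(np.float64)
    else:
        codes, vals = np.empty(0, dtype=np.int64), np.empty(0)
    return CooccurrenceTensor(
        codes=codes, vals=vals, n_levels=n, distance=meta["distance"],
        directions=tuple(meta["directions"]), symmetric=meta["symmetric"],
        normalized=meta["normalized"], empty=codes.size == 0,
    )
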