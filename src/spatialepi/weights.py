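"""Spatial contiguity weights.

Builds the sparse weight matrix W that every downstream statistic consumes:
queen contiguity (units are neighbors if their boundaries share at least one
point), the stronger shared-border variant (a positive-length common segment,
which excludes corner-only contact), direct construction from adjacency
pairs, row standardization, and the spatial lag operator.

Units with no neighbors ("islands", e.g. archipelago districts) are kept in
the matrix as zero rows, recorded, and excluded from local classification
downstream rather than dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from shapely import set_precision
from shapely.strtree import STRtree

from .errors import DegenerateInputError, FormatError
from .geo_io import SpatialFrame

__all__ = [
    "WeightMatrix",
    "queen_adjacency",
    "shared_border_adjacency",
    "from_adjacency_pairs",
    "row_standardize",
    "spatial_lag",
]

DEFAULT_SNAP_TOLERANCE = 1e-7


@dataclass(eq=False)
class WeightMatrix:
    """Sparse spatial weights over an ordered set of units.

    ``matrix`` is an n x n CSR matrix with zero diagonal; ``style`` is
    "binary" (symmetric 0/1) or "row_standardized" (non-island rows sum
    to 1).  ``s0`` is the aggregate of all weights, the S_0 normalizer of
    Moran's I.
    """

    ids: list[str]
    matrix: sp.csr_matrix
    style: str = "binary"
    _eigenvalues: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise FormatError("weight matrix shape does not match id count")
        if self.style not in ("binary", "row_standardized"):
            raise FormatError(f"unknown weight style {self.style!r}")
        diag = self.matrix.diagonal()
        if np.any(diag != 0):
            raise FormatError("weight matrix must have a zero diagonal")
        self._index = {uid: i for i, uid in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())

    @property
    def islands(self) -> set[str]:
        deg = np.asarray(self.matrix.getnnz(axis=1))
        return {self.ids[i] for i in np.flatnonzero(deg == 0)}

    @property
    def island_mask(self) -> np.ndarray:
        return np.asarray(self.matrix.getnnz(axis=1)) == 0

    def neighbors(self, unit_id: str) -> list[str]:
        i = self._index[unit_id]
        row = self.matrix.getrow(i)
        return [self.ids[j] for j in row.indices]

    def neighbor_pairs(self) -> list[tuple[str, str]]:
        """Undirected neighbor pairs (i < j in frame order)."""
        coo = self.matrix.tocoo()
        return sorted(
            (self.ids[i], self.ids[j]) for i, j in zip(coo.row, coo.col) if i < j
        )

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of W (cached), used for SAR log-determinants.

        A row-standardized matrix derived from symmetric binary contiguity is
        similar to the symmetric D^{-1/2} A D^{-1/2}, so its spectrum is real
        and computed exactly with a symmetric solver; otherwise the general
        solver is used and any residual imaginary parts are discarded with a
        warning.
        """
        if self._eigenvalues is not None:
            return self._eigenvalues
        dense = self.matrix.toarray()
        if np.allclose(dense, dense.T):
            vals = scipy.linalg.eigvalsh(dense)
        else:
            sym = self._symmetric_similar(dense)
            if sym is not None:
                vals = scipy.linalg.eigvalsh(sym)
            else:
                cvals = scipy.linalg.eigvals(dense)
                if np.max(np.abs(cvals.imag)) > 1e-8 * max(1.0, np.max(np.abs(cvals))):
                    warnings.warn(
                        "weight matrix has complex eigenvalues; using real parts "
                        "as the admissible-interval bound"
                    )
                vals = cvals.real
        self._eigenvalues = np.sort(vals)
        return self._eigenvalues

    def _symmetric_similar(self, dense: np.ndarray) -> Optional[np.ndarray]:
        # detect W = D^{-1} A with A symmetric binary; return D^{-1/2} A D^{-1/2}
        deg = (dense > 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = dense * deg[:, None]
        a[deg == 0, :] = 0.0
        if not (np.allclose(a[a > 0], 1.0) and np.allclose(a, a.T)):
            return None
        inv_sqrt = np.zeros_like(deg, dtype=float)
        inv_sqrt[deg > 0] = 1.0 / np.sqrt(deg[deg > 0])
        return a * inv_sqrt[:, None] * inv_sqrt[None, :]

    def spatial_parameter_interval(self) -> tuple[float, float]:
        """Open interval of admissible SAR parameters (1/w_min, 1/w_max)."""
        vals = self.eigenvalues()
        w_min, w_max = float(vals[0]), float(vals[-1])
        if self.style == "row_standardized" and abs(w_max - 1.0) < 1e-8:
            # the exact largest eigenvalue is 1; do not let float noise
            # push the admissible bound above it
            w_max = 1.0
        if w_max <= 0:
            raise DegenerateInputError("weight matrix has no positive eigenvalue")
        lo = 1.0 / w_min if w_min < 0 else -np.inf
        return lo, 1.0 / w_max


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def _contiguity(frame: SpatialFrame, snap_tolerance: float, shared_border: bool
                ) -> WeightMatrix:
    if frame.n < 2:
        raise DegenerateInputError("contiguity needs at least 2 units")
    if snap_tolerance < 0:
        raise FormatError("snap_tolerance must be >= 0")
    geoms = frame.geometries
    if snap_tolerance > 0:
        geoms = [set_precision(g, snap_tolerance) for g in geoms]
    for uid, g in zip(frame.ids, geoms):
        if g.is_empty or g.area == 0:
            warnings.warn(f"unit {uid!r} has degenerate (zero-area) geometry")
    tree = STRtree(geoms)
    rows, cols = [], []
    for i, geom in enumerate(geoms):
        for j in tree.query(geom, predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            if shared_border:
                seg = geoms[i].boundary.intersection(geoms[j].boundary)
                if seg.is_empty or seg.length == 0:
                    continue
            rows.extend((i, j))
            cols.extend((j, i))
    data = np.ones(len(rows))
    mat = sp.csr_matrix((data, (rows, cols)), shape=(frame.n, frame.n))
    return WeightMatrix(ids=list(frame.ids), matrix=mat, style="binary")


def queen_adjacency(frame: SpatialFrame,
                    snap_tolerance: float = DEFAULT_SNAP_TOLERANCE) -> WeightMatrix:
    """Queen contiguity: w_ij = 1 iff boundaries share at least one point.

    Vertices are snapped to a grid of pitch ``snap_tolerance`` before the
    intersection tests, absorbing the sub-micron vertex mismatch real
    boundary files routinely carry.
    """
    return _contiguity(frame, snap_tolerance, shared_border=False)


def shared_border_adjacency(frame: SpatialFrame,
                            snap_tolerance: float = DEFAULT_SNAP_TOLERANCE
                            ) -> WeightMatrix:
    """Rook-like contiguity: w_ij = 1 iff a positive-length border is shared.

    A strictly stronger condition than queen: corner-only contact (a shared
    point on a grid of units) does not count.
    """
    return _contiguity(frame, snap_tolerance, shared_border=True)


def from_adjacency_pairs(ids: Iterable[str], pairs: Iterable[tuple[str, str]]
                         ) -> WeightMatrix:
    """Binary weights from an explicit undirected pair list (bypasses geometry)."""
    ids = list(ids)
    index = {uid: i for i, uid in enumerate(ids)}
    if len(index) != len(ids):
        raise FormatError("duplicate unit ids")
    rows, cols = [], []
    for a, b in pairs:
        if a not in index:
            raise FormatError(f"unknown id {a!r} in adjacency pair")
        if b not in index:
            raise FormatError(f"unknown id {b!r} in adjacency pair")
        if a == b:
            raise FormatError(f"self-pair ({a!r}, {a!r}) is not allowed")
        rows.extend((index[a], index[b]))
        cols.extend((index[b], index[a]))
    n = len(ids)
    mat = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    mat.data[:] = 1.0  # symmetric closure; duplicate pairs collapse to 1
    return WeightMatrix(ids=ids, matrix=mat, style="binary")


def row_standardize(weights: WeightMatrix) -> WeightMatrix:
    """Divide each non-island row by its sum so the lag is a neighbor mean."""
    if weights.style == "row_standardized":
        return weights
    mat = weights.matrix.tocsr(copy=True).astype(float)
    row_sums = np.asarray(mat.sum(axis=1)).ravel()
    scale = np.ones_like(row_sums)
    nz = row_sums > 0
    scale[nz] = 1.0 / row_sums[nz]
    mat = sp.diags(scale) @ mat
    return WeightMatrix(ids=list(weights.ids), matrix=mat.tocsr(),
                        style="row_standardized")


def spatial_lag(weights: WeightMatrix, x: np.ndarray) -> np.ndarray:
    """The lag vector (Wx)_i = sum_j w_ij x_j; a neighbor mean when W is
    row-standardized.  Islands get 0."""
    x = np.asarray(x, dtype=float)
    if x.shape != (weights.n,):
        raise FormatError(f"vector length {x.shape} does not match n={weights.n}")
    return weights.matrix @ x
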