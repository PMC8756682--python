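"""Local indicators of spatial association (LISA) and cluster maps.

The univariate local Moran at unit i is

    I_i = [n (x_i - xbar) / sum_i (x_i - xbar)^2] * sum_j w_ij (x_j - xbar)

which, written on the z-scored variable, is simply z_i * (Wz)_i; its sum
over units equals S0 times the global statistic.  The bivariate form is
I_i = zx_i * (W zy)_i on z-scored variables.

Each unit falls in one quadrant of the Moran scatterplot by the signs of
its standardized value and standardized neighbor lag: (+,+) HH, (-,-) LL,
(+,-) HL, (-,+) LH.  Significance is assessed by conditional permutation
(hold the unit's own value fixed, re-draw its neighbors' values from the
remaining units R times), and significant quadrants become the map labels:
hotspot (HH), coldspot (LL), and the two spatial-outlier classes.
Neighborless units are labelled "island" and never classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DegenerateInputError, FormatError
from .global_moran import MIN_PERMUTATIONS, _check_vector, _check_weights, _zscore
from .weights import WeightMatrix

__all__ = ["LocalMoranStats", "local_moran", "local_moran_bivariate",
           "conditional_permutation", "classify_clusters", "cluster_counts",
           "lisa", "CLUSTER_LABELS"]

CLUSTER_LABELS = ("hotspot", "coldspot", "high_low_outlier",
                  "low_high_outlier", "not_significant", "island")

_QUADRANT_LABEL = {"HH": "hotspot", "LL": "coldspot",
                   "HL": "high_low_outlier", "LH": "low_high_outlier"}


@dataclass
class LocalMoranStats:
    """Per-unit LISA values plus the run's inferential settings."""

    ids: list[str]
    local_i: np.ndarray
    z_value: np.ndarray      # standardized variable at i
    lag_value: np.ndarray    # standardized neighbor lag at i
    quadrant: list           # "HH"/"LL"/"HL"/"LH", None for islands
    pseudo_p: np.ndarray     # nan until permutation ran / for islands
    cluster_label: list
    variable_x: str = "x"
    variable_y: Optional[str] = None
    alpha: Optional[float] = None
    permutations: int = 0
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def island_mask(self) -> np.ndarray:
        return np.array([lbl == "island" for lbl in self.cluster_label])


def _quadrants(z: np.ndarray, lag: np.ndarray, islands: np.ndarray) -> list:
    # zero is tie-broken to the "low" side
    out = []
    for zi, li, isl in zip(z, lag, islands):
        if isl:
            out.append(None)
        else:
            out.append(("H" if zi > 0 else "L") + ("H" if li > 0 else "L"))
    return out


def _build_stats(weights: WeightMatrix, zx: np.ndarray, zy: np.ndarray,
                 variable_x: str, variable_y: Optional[str]) -> LocalMoranStats:
    islands = weights.island_mask
    lag = weights.matrix @ zy
    local_i = zx * lag
    local_i = np.where(islands, 0.0, local_i)
    pseudo_p = np.full(weights.n, np.nan)
    labels = ["island" if isl else "not_significant" for isl in islands]
    return LocalMoranStats(
        ids=list(weights.ids), local_i=local_i, z_value=zx, lag_value=lag,
        quadrant=_quadrants(zx, lag, islands), pseudo_p=pseudo_p,
        cluster_label=labels, variable_x=variable_x, variable_y=variable_y,
    )


def local_moran(weights: WeightMatrix, x, variable_name: str = "x"
                ) -> LocalMoranStats:
    """Univariate local Moran I_i for every unit (no inference yet)."""
    x = _check_vector(weights, x, variable_name)
    _check_weights(weights)
    zs = _zscore(x)
    return _build_stats(weights, zs, zs, variable_name, None)


def local_moran_bivariate(weights: WeightMatrix, x, y,
                          variable_x: str = "x", variable_y: str = "y"
                          ) -> LocalMoranStats:
    """Bivariate local Moran I_i = zx_i * (W zy)_i on z-scored variables."""
    x = _check_vector(weights, x, variable_x)
    y = _check_vector(weights, y, variable_y)
    _check_weights(weights)
    return _build_stats(weights, _zscore(x), _zscore(y), variable_x, variable_y)


def conditional_permutation(weights: WeightMatrix, x, y=None,
                            permutations: int = 999,
                            seed: Optional[int] = None) -> np.ndarray:
    """Per-unit pseudo p-values by conditional permutation.

    For each unit i its own value is held fixed while the remaining n-1
    values are randomly re-assigned to its neighbors R times; the pseudo p
    is (m_i + 1)/(R + 1) with m_i the count of null draws at least as far
    from their mean as the observed I_i (the same calibrated extremeness
    rule as the global test).  One random index matrix is drawn and shared
    across units (truncated to each unit's degree), the standard trick that
    keeps the test O(R * sum k_i).  Islands get nan.
    """
    if permutations < MIN_PERMUTATIONS:
        raise FormatError(
            f"permutations must be >= {MIN_PERMUTATIONS}, got {permutations}"
        )
    x = _check_vector(weights, x, "x")
    _check_weights(weights)
    zx = _zscore(x)
    zy = zx if y is None else _zscore(_check_vector(weights, y, "y"))
    observed = np.where(weights.island_mask, 0.0, zx * (weights.matrix @ zy))

    n = weights.n
    mat = weights.matrix
    degrees = np.diff(mat.indptr)
    max_k = int(degrees.max())
    rng = np.random.default_rng(seed)
    rids = np.argsort(rng.random((permutations, n - 1)), axis=1)[:, :max_k]

    pseudo_p = np.full(n, np.nan)
    all_idx = np.arange(n)
    for i in range(n):
        k = degrees[i]
        if k == 0:
            continue
        w_row = mat.data[mat.indptr[i]:mat.indptr[i + 1]]
        others = np.delete(all_idx, i)
        sampled = zy[others[rids[:, :k]]]          # (R, k)
        null_i = zx[i] * (sampled @ w_row)         # (R,)
        center = null_i.mean()
        m = int(np.sum(np.abs(null_i - center) >= abs(observed[i] - center)))
        pseudo_p[i] = (m + 1) / (permutations + 1)
    return pseudo_p


def classify_clusters(stats: LocalMoranStats, alpha: float = 0.05
                      ) -> LocalMoranStats:
    """Fill cluster labels from quadrants and pseudo p-values.

    Significant (pseudo_p <= alpha) HH units become hotspots, LL coldspots,
    HL/LH the two outlier classes; everything else is not_significant.
    Islands are left untouched.
    """
    if not (0 < alpha < 1):
        raise FormatError(f"alpha must be in (0, 1), got {alpha}")
    labels = []
    for quad, p, old in zip(stats.quadrant, stats.pseudo_p, stats.cluster_label):
        if old == "island":
            labels.append("island")
        elif np.isfinite(p) and p <= alpha:
            labels.append(_QUADRANT_LABEL[quad])
        else:
            labels.append("not_significant")
    return replace(stats, cluster_label=labels, alpha=alpha)


def cluster_counts(stats: LocalMoranStats) -> dict[str, int]:
    """Label -> count over all six labels; counts sum to n."""
    counts = {label: 0 for label in CLUSTER_LABELS}
    for label in stats.cluster_label:
        counts[label] += 1
    return counts


def lisa(weights: WeightMatrix, x, y=None, variable_x: str = "x",
         variable_y: Optional[str] = None, permutations: int = 999,
         seed: Optional[int] = None, alpha: float = 0.05) -> LocalMoranStats:
    """One-call LISA: statistic, conditional permutation, classification."""
    if y is None:
        stats = local_moran(weights, x, variable_x)
    else:
        stats = local_moran_bivariate(weights, x, y, variable_x,
                                      variable_y or "y")
    stats.pseudo_p = conditional_permutation(weights, x, y, permutations, seed)
    stats.permutations = permutations
    stats.seed = seed
    return classify_clusters(stats, alpha)
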