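"""Group-level correlation networks and sparsity thresholding.

Metabolic connectivity is inter-subject: within one group, the edge weight
between regions i and j is the Pearson correlation of their SUV values
across that group's subjects. The weighted network is binarized over a grid
of sparsities (fraction of possible edges retained), yielding a nested
stack of undirected, unweighted graphs with identical edge counts across
groups at each sparsity.

Edges are ranked by SIGNED correlation (most positive first) by default —
connectivity is treated as positive coupling, the common convention for
binarized association networks; absolute-value ranking is available via
``ranking="absolute"``. Ties at a threshold cut are broken deterministically
by higher |r|, then lexicographic (i, j) region order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._util import UnionFind, round_half_away
from .suv_io import SUVTable

logger = logging.getLogger(__name__)

__all__ = [
    "GroupNetwork",
    "SparsityGrid",
    "BinaryGraphStack",
    "default_grid",
    "group_correlation",
    "ranked_edges",
    "threshold_sparsity",
    "build_stack",
    "min_density_connected",
]


@dataclass(frozen=True)
class GroupNetwork:
    """Symmetric region x region Pearson correlation matrix, diagonal 0."""

    matrix: np.ndarray
    group_id: str
    n_subjects: int
    region_names: tuple[str, ...] = ()

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be stored as 0 (self-edges excluded)")
        if np.nanmax(np.abs(m)) > 1 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pairs(self) -> int:
        n = self.n_regions
        return n * (n - 1) // 2


@dataclass(frozen=True)
class SparsityGrid:
    """Ordered sparsity values; default 0.05..0.50 step 0.01 (46 values)."""

    values: tuple[float, ...]

    def __post_init__(self):
        v = np.asarray(self.values)
        if len(v) == 0 or np.any(v <= 0) or np.any(v >= 1):
            raise ValueError("sparsities must lie in (0, 1)")
        if np.any(np.diff(v) <= 0):
            raise ValueError("sparsities must be strictly increasing")

    def __len__(self):
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def default_grid() -> SparsityGrid:
    return SparsityGrid(tuple(np.round(np.arange(5, 51) / 100.0, 2)))


@dataclass
class BinaryGraphStack:
    """One binary adjacency per sparsity, nested (top-k thresholding)."""

    grid: SparsityGrid
    adjacencies: list[np.ndarray]
    group_id: str = ""

    def __post_init__(self):
        if len(self.adjacencies) != len(self.grid):
            raise ValueError("one adjacency per grid value required")

    def edge_counts(self) -> list[int]:
        return [int(a.sum() // 2) for a in self.adjacencies]


def group_correlation(table: SUVTable, group: str) -> GroupNetwork:
    """Pearson correlation of each pair of regions across the group's
    subjects; diagonal zeroed. Refuses zero-variance regions by name."""
    x = table.group_values(group)
    n_subjects = x.shape[0]
    if n_subjects < 4:
        raise ValueError(f"group {group!r} has {n_subjects} subjects; need >= 4")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        names = list(table.data.columns)
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance regions in group {group!r}: {bad} (r undefined)")
    m = np.corrcoef(x.T)
    m = np.clip((m + m.T) / 2, -1.0, 1.0)
    np.fill_diagonal(m, 0.0)
    return GroupNetwork(matrix=m, group_id=group, n_subjects=n_subjects,
                        region_names=tuple(table.data.columns))


def ranked_edges(matrix: np.ndarray, ranking: str = "signed"):
    """All upper-triangle edges sorted by retention priority.

    Returns (i_idx, j_idx, weights) sorted most-retainable first:
    descending signed r (or |r|), ties by higher |r| then lexicographic
    (i, j). Deterministic.
    """
    n = matrix.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = matrix[iu, ju]
    key = w if ranking == "signed" else np.abs(w)
    if ranking not in ("signed", "absolute"):
        raise ValueError(f"unknown ranking {ranking!r}")
    # lexsort: last key is primary
    order = np.lexsort((ju, iu, -np.abs(w), -key))
    return iu[order], ju[order], w[order]


def _k_edges(s: float, n_pairs: int) -> int:
    k = round_half_away(s * n_pairs)
    return max(1, min(k, n_pairs))


def threshold_sparsity(net: GroupNetwork, s: float, ranking: str = "signed") -> np.ndarray:
    """Binarize keeping exactly round(s * n_pairs) top-ranked edges."""
    if not 0 < s < 1:
        raise ValueError(f"sparsity {s} outside (0, 1)")
    i, j, w = ranked_edges(net.matrix, ranking)
    k = _k_edges(s, net.n_pairs)
    if k < len(w) and w[k - 1] == w[k]:
        logger.warning("tie at sparsity %.3f cut (r=%.6f); resolved by (|r|, i, j) order",
                       s, w[k])
    adj = np.zeros_like(net.matrix, dtype=bool)
    adj[i[:k], j[:k]] = True
    adj |= adj.T
    if ranking == "signed" and w[k - 1] < 0:
        logger.info("negative-r edges entered at sparsity %.3f (min retained r=%.4f)",
                    s, w[k - 1])
    return adj


def build_stack(net: GroupNetwork, grid: SparsityGrid | None = None,
                ranking: str = "signed") -> BinaryGraphStack:
    """One binary adjacency per grid sparsity, built cumulatively so the
    stack is nested by construction."""
    grid = grid or default_grid()
    i, j, w = ranked_edges(net.matrix, ranking)
    adj = np.zeros_like(net.matrix, dtype=bool)
    out = []
    prev_k = 0
    for s in grid:
        k = _k_edges(s, net.n_pairs)
        adj[i[prev_k:k], j[prev_k:k]] = True
        adj[j[prev_k:k], i[prev_k:k]] = True
        prev_k = max(prev_k, k)
        out.append(adj.copy())
    return BinaryGraphStack(grid=grid, adjacencies=out, group_id=net.group_id)


def iter_stack(matrix: np.ndarray, grid: SparsityGrid, ranking: str = "signed"):
    """Yield the cumulative binary adjacency at each grid sparsity without
    storing the whole stack. The SAME array object is yielded each time
    (mutated in place); callers must not retain or mutate it.
    """
    n = matrix.shape[0]
    n_pairs = n * (n - 1) // 2
    i, j, _ = ranked_edges(matrix, ranking)
    adj = np.zeros((n, n), dtype=bool)
    prev_k = 0
    for s in grid:
        k = _k_edges(s, n_pairs)
        adj[i[prev_k:k], j[prev_k:k]] = True
        adj[j[prev_k:k], i[prev_k:k]] = True
        prev_k = max(prev_k, k)
        yield adj


def min_density_connected(net: GroupNetwork, active_nodes=None,
                          ranking: str = "signed"):
    """Threshold the (sub)network at the minimum density giving a fully
    connected graph.

    Restricted to ``active_nodes``, edges are added in descending
    correlation order until the graph is connected. Returns
    (density, adjacency over active_nodes in their given order).
    """
    if active_nodes is None:
        active = np.arange(net.n_regions)
    else:
        active = np.asarray(active_nodes)
    a = len(active)
    if a < 2:
        raise ValueError("need at least 2 active nodes")
    sub = net.matrix[np.ix_(active, active)]
    i, j, w = ranked_edges(sub, ranking)
    uf = UnionFind(a)
    adj = np.zeros((a, a), dtype=bool)
    kept = 0
    for e in range(len(w)):
        adj[i[e], j[e]] = adj[j[e], i[e]] = True
        kept += 1
        uf.union(int(i[e]), int(j[e]))
        if uf.n_components == 1:
            break
    density = kept / (a * (a - 1) / 2)
    return density, adj
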