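"""Global and nodal graph-theory metrics on binary undirected networks.

Conventions (chosen to match common connectome practice on thresholded
binary networks, and stated so oracles agree):

* Characteristic path length Lp averages shortest-path length over the
  connected node pairs only; disconnected pairs are excluded (not infinite,
  not largest-component-only), keeping Lp defined at low sparsity. With no
  connected pair at all, Lp is NaN (the undefined marker).
* Efficiencies use 1/d with 1/inf = 0 for disconnected pairs, so E_glob,
  E_loc and E_nod are always defined and lie in [0, 1].
* Clustering per node with degree < 2 contributes 0 (not excluded) to the
  Cp and E_loc means over ALL nodes.
* Betweenness centrality is unnormalized, undirected (each unordered pair
  counted once). Group comparisons are scale-invariant to this choice.
* The random null ensemble is Maslov-Sneppen degree-preserving double-edge
  swapping (10 x edge-count swap attempts per graph by default); gamma =
  Cp/<Cp_rand>, lambda = Lp/<Lp_rand>, small-worldness sigma = gamma/lambda.

Shortest-path distances are computed by a vectorized BFS (boolean matrix
closure); betweenness and rewiring are delegated to igraph's C routines.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np

from ._util import child_seed
from .network import BinaryGraphStack, SparsityGrid, default_grid, iter_stack

__all__ = [
    "distance_matrix",
    "characteristic_path_length",
    "clustering_coefficient",
    "global_efficiency",
    "local_efficiency",
    "node_degree",
    "betweenness_centrality",
    "nodal_efficiency",
    "rewire_degree_preserving",
    "small_world",
    "RandomEnsembleStats",
    "SmallWorldResult",
    "GlobalMetrics",
    "global_metrics",
    "auc_over_grid",
    "MetricCurve",
    "metric_curve",
    "global_curves_from_stack",
    "global_curves_from_matrix",
    "nodal_curves_from_stack",
    "nodal_curves_from_matrix",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
]

GLOBAL_METRICS = ("Lp", "Cp", "Eglob", "Eloc", "gamma", "lambda", "sigma")
NODAL_METRICS = ("D", "BC", "Enod")


def _as_bool(adj) -> np.ndarray:
    a = np.asarray(adj)
    a = a.astype(bool) if a.dtype != bool else a
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    return a


def distance_matrix(adj) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths; inf for disconnected
    pairs. Vectorized BFS: hop-k reachability via repeated matmul."""
    a = _as_bool(adj)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    if n == 0 or not a.any():
        return dist
    dist[a] = 1.0
    af = a.astype(np.float32)
    reach = a | np.eye(n, dtype=bool)
    k = 1
    while True:
        k += 1
        new_reach = (reach.astype(np.float32) @ af) > 0
        newly = new_reach & ~reach
        if not newly.any():
            break
        dist[newly] = k
        reach |= new_reach
    return dist


def characteristic_path_length(adj, dist: np.ndarray | None = None) -> float:
    """Mean shortest-path length over connected node pairs; NaN if no pair
    is connected (the undefined marker, not an exception)."""
    a = _as_bool(adj)
    if a.shape[0] < 2:
        return float("nan")
    d = distance_matrix(a) if dist is None else dist
    iu = np.triu_indices(a.shape[0], 1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return float("nan")
    return float(finite.mean())


def clustering_coefficient(adj):
    """Per-node clustering (edges among neighbors / possible) and the mean
    over ALL nodes; degree < 2 contributes 0."""
    a = _as_bool(adj)
    # float32 matmul is exact here (counts < 2^24) and measurably faster in
    # the permutation loops; divide in float64
    af = a.astype(np.float32)
    deg = af.sum(1, dtype=np.float64)
    # (A^3)_ii = 2 * triangles through i
    paths3 = np.einsum("ij,ji->i", af @ af, af).astype(np.float64)
    denom = deg * (deg - 1)
    c = np.divide(paths3, denom, out=np.zeros_like(deg), where=denom > 0)
    return c, float(c.mean()) if a.shape[0] else 0.0


def global_efficiency(adj, dist: np.ndarray | None = None) -> float:
    """Mean over unordered pairs of 1/d, with 1/inf = 0."""
    a = _as_bool(adj)
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = distance_matrix(a) if dist is None else dist
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(adj, dist: np.ndarray | None = None) -> np.ndarray:
    """Per node, mean over other nodes of 1/d (1/inf = 0)."""
    a = _as_bool(adj)
    n = a.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency needs >= 2 nodes")
    d = distance_matrix(a) if dist is None else dist
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    return inv.sum(1) / (n - 1)


def local_efficiency(adj):
    """Per node, global efficiency of the subgraph induced by its
    neighbors (degree < 2 contributes 0); plus the mean over all nodes."""
    a = _as_bool(adj)
    n = a.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        vals[i] = global_efficiency(a[np.ix_(nb, nb)])
    return vals, float(vals.mean()) if n else 0.0


def node_degree(adj) -> np.ndarray:
    return _as_bool(adj).sum(1).astype(int)


def _to_igraph(adj) -> ig.Graph:
    a = _as_bool(adj)
    ii, jj = np.nonzero(np.triu(a, 1))
    return ig.Graph(a.shape[0], list(zip(ii.tolist(), jj.tolist())))


def betweenness_centrality(adj) -> np.ndarray:
    """Unnormalized undirected betweenness (each unordered pair once)."""
    a = _as_bool(adj)
    if a.shape[0] < 2:
        raise ValueError("betweenness needs >= 2 nodes")
    return np.asarray(_to_igraph(a).betweenness(), dtype=float)


def rewire_degree_preserving(adj, n_swap_per_edge: int = 10, seed: int | None = None):
    """Degree-preserving randomization by repeated double-edge swaps,
    rejecting self-loops and multi-edges. Same seed -> identical output.

    A graph admitting no valid swap (complete, or < 2 edges) is returned
    unchanged with a warning.
    """
    a = _as_bool(adj)
    n = a.shape[0]
    m = int(a.sum() // 2)
    if m < 2 or m == n * (n - 1) // 2:
        warnings.warn("graph admits no degree-preserving swap; returned unchanged")
        return a.copy()
    g = _to_igraph(a)
    try:
        ig.set_random_number_generator(_pyrandom.Random(
            child_seed(seed, "rewire") if seed is not None else None))
        g.rewire(n=n_swap_per_edge * m)
    finally:
        ig.set_random_number_generator(_pyrandom)
    out = np.zeros((n, n), dtype=bool)
    edges = np.asarray(g.get_edgelist())
    out[edges[:, 0], edges[:, 1]] = True
    out |= out.T
    return out


@dataclass(frozen=True)
class RandomEnsembleStats:
    mean_Cp_rand: float
    mean_Lp_rand: float
    ensemble_size: int


@dataclass(frozen=True)
class SmallWorldResult:
    gamma: float
    lam: float
    sigma: float
    ensemble: RandomEnsembleStats


def small_world(adj, ensemble_size: int = 5000, seed: int | None = None,
                n_swap_per_edge: int = 10) -> SmallWorldResult:
    """Normalized clustering gamma = Cp/<Cp_rand>, normalized path length
    lambda = Lp/<Lp_rand> against ``ensemble_size`` degree-matched rewired
    networks, and sigma = gamma/lambda (exactly).

    Each ensemble member uses a named child seed of ``seed``.
    """
    a = _as_bool(adj)
    m = int(a.sum() // 2)
    if m < 2:
        raise ValueError("small-world metrics need >= 2 edges")
    _, cp = clustering_coefficient(a)
    lp = characteristic_path_length(a)
    g0 = _to_igraph(a)
    cps = np.empty(ensemble_size)
    lps = np.empty(ensemble_size)
    complete = m == a.shape[0] * (a.shape[0] - 1) // 2
    try:
        for r in range(ensemble_size):
            g = g0.copy()
            if not complete:
                ig.set_random_number_generator(_pyrandom.Random(
                    child_seed(seed, "ensemble", r) if seed is not None else None))
                g.rewire(n=n_swap_per_edge * m)
            # igraph conventions match ours: local transitivity with
            # degree<2 -> 0, path length averaged over connected pairs
            cps[r] = np.mean(g.transitivity_local_undirected(mode="zero"))
            lps[r] = g.average_path_length(unconn=True)
    finally:
        ig.set_random_number_generator(_pyrandom)
    mean_cp_rand = float(cps.mean())
    mean_lp_rand = float(lps.mean())
    stats = RandomEnsembleStats(mean_cp_rand, mean_lp_rand, ensemble_size)
    if mean_cp_rand == 0:
        warnings.warn("ensemble mean clustering is 0; gamma and sigma undefined")
        gamma = float("nan")
    else:
        gamma = cp / mean_cp_rand
    lam = lp / mean_lp_rand if mean_lp_rand > 0 else float("nan")
    sigma = gamma / lam
    return SmallWorldResult(gamma=gamma, lam=lam, sigma=sigma, ensemble=stats)


@dataclass(frozen=True)
class GlobalMetrics:
    Lp: float
    Cp: float
    Eglob: float
    Eloc: float
    gamma: float = float("nan")
    lam: float = float("nan")
    sigma: float = float("nan")

    def as_dict(self) -> dict:
        return {"Lp": self.Lp, "Cp": self.Cp, "Eglob": self.Eglob,
                "Eloc": self.Eloc, "gamma": self.gamma, "lambda": self.lam,
                "sigma": self.sigma}


def global_metrics(adj, ensemble_size: int | None = None,
                   seed: int | None = None) -> GlobalMetrics:
    """All global metrics of one binary network; gamma/lambda/sigma only if
    ``ensemble_size`` is given."""
    a = _as_bool(adj)
    d = distance_matrix(a)
    _, cp = clustering_coefficient(a)
    _, eloc = local_efficiency(a)
    out = dict(Lp=characteristic_path_length(a, d), Cp=cp,
               Eglob=global_efficiency(a, d), Eloc=eloc)
    if ensemble_size:
        sw = small_world(a, ensemble_size=ensemble_size, seed=seed)
        out.update(gamma=sw.gamma, lam=sw.lam, sigma=sw.sigma)
    return GlobalMetrics(**out)


def auc_over_grid(values, grid: SparsityGrid | np.ndarray) -> float:
    """Trapezoidal area of a metric curve over the sparsity grid.

    NaN values (undefined markers) are dropped together with their grid
    points, with a warning; fewer than 2 points is an error.
    """
    s = grid.as_array() if isinstance(grid, SparsityGrid) else np.asarray(grid, float)
    v = np.asarray(values, dtype=float)
    if v.shape != s.shape:
        raise ValueError("values and grid lengths differ")
    if s.size < 2:
        raise ValueError("AUC needs at least 2 grid points")
    ok = np.isfinite(v)
    if not ok.all():
        warnings.warn(f"AUC: dropping {int((~ok).sum())} undefined grid points")
    if ok.sum() < 2:
        raise ValueError("AUC needs at least 2 finite values")
    return float(np.trapezoid(v[ok], s[ok]))


@dataclass(frozen=True)
class MetricCurve:
    grid: SparsityGrid
    values: np.ndarray
    auc: float


def metric_curve(stack: BinaryGraphStack, metric: str,
                 ensemble_size: int = 100, seed: int | None = None) -> MetricCurve:
    """One global metric evaluated at every sparsity of a stack, plus its
    AUC. gamma/lambda/sigma use ``ensemble_size`` rewired nulls per layer."""
    curves = global_curves_from_stack(stack, (metric,), ensemble_size, seed)
    vals = curves[metric]
    return MetricCurve(grid=stack.grid, values=vals, auc=auc_over_grid(vals, stack.grid))


def global_curves_from_stack(stack: BinaryGraphStack, metrics=GLOBAL_METRICS,
                             ensemble_size: int = 100,
                             seed: int | None = None) -> dict[str, np.ndarray]:
    """Global metric values per sparsity layer for the requested metrics.

    Computes shared intermediates (distance matrix) once per layer.
    """
    return _global_curves(stack.adjacencies, len(stack.grid), metrics,
                          ensemble_size, seed)


def global_curves_from_matrix(matrix: np.ndarray, grid: SparsityGrid,
                              metrics=GLOBAL_METRICS, ranking: str = "signed",
                              ensemble_size: int = 100,
                              seed: int | None = None) -> dict[str, np.ndarray]:
    """As global_curves_from_stack, but thresholding a weighted correlation
    matrix on the fly (the permutation-loop fast path)."""
    return _global_curves(iter_stack(matrix, grid, ranking), len(grid),
                          metrics, ensemble_size, seed)


def _global_curves(adjacencies, n_layers, metrics, ensemble_size, seed):
    metrics = tuple(metrics)
    unknown = set(metrics) - set(GLOBAL_METRICS)
    if unknown:
        raise ValueError(f"unknown global metrics: {sorted(unknown)}")
    need_dist = bool({"Lp", "Eglob"} & set(metrics))
    need_sw = bool({"gamma", "lambda", "sigma"} & set(metrics))
    out = {m: np.empty(n_layers) for m in metrics}
    for li, adj in enumerate(adjacencies):
        d = distance_matrix(adj) if need_dist else None
        vals = {}
        if need_sw:
            sw = small_world(adj, ensemble_size=ensemble_size,
                             seed=child_seed(seed, "layer", li) if seed is not None else None)
            vals.update({"gamma": sw.gamma, "lambda": sw.lam, "sigma": sw.sigma})
        if "Lp" in metrics:
            vals["Lp"] = characteristic_path_length(adj, d)
        if "Eglob" in metrics:
            vals["Eglob"] = global_efficiency(adj, d)
        if "Cp" in metrics:
            vals["Cp"] = clustering_coefficient(adj)[1]
        if "Eloc" in metrics:
            vals["Eloc"] = local_efficiency(adj)[1]
        for m in metrics:
            out[m][li] = vals[m]
    return out


def nodal_curves_from_stack(stack: BinaryGraphStack,
                            metrics=NODAL_METRICS) -> dict[str, np.ndarray]:
    """Nodal metric values per sparsity layer: arrays (n_layers, n_nodes)."""
    n = stack.adjacencies[0].shape[0]
    return _nodal_curves(stack.adjacencies, len(stack.grid), n, metrics)


def nodal_curves_from_matrix(matrix: np.ndarray, grid: SparsityGrid,
                             metrics=NODAL_METRICS,
                             ranking: str = "signed") -> dict[str, np.ndarray]:
    """As nodal_curves_from_stack, thresholding a weighted matrix on the fly."""
    return _nodal_curves(iter_stack(matrix, grid, ranking), len(grid),
                         matrix.shape[0], metrics)


def _nodal_curves(adjacencies, n_layers, n, metrics):
    metrics = tuple(metrics)
    unknown = set(metrics) - set(NODAL_METRICS)
    if unknown:
        raise ValueError(f"unknown nodal metrics: {sorted(unknown)}")
    out = {m: np.empty((n_layers, n)) for m in metrics}
    for li, adj in enumerate(adjacencies):
        if "D" in metrics:
            out["D"][li] = node_degree(adj)
        if "Enod" in metrics:
            out["Enod"][li] = nodal_efficiency(adj)
        if "BC" in metrics:
            out["BC"][li] = betweenness_centrality(adj)
    return out
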