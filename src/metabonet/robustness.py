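"""Network robustness under random failure and targeted attack.

Nodes are removed one at a time, either in uniformly random order (repeated
over several independent orderings and averaged) or in descending order of
betweenness centrality computed once on the intact network (a static
ranking; the ordering is NOT recomputed after each removal). After each
removal step:

* the surviving nodes' weighted correlation submatrix is re-thresholded at
  the minimum density giving full connectivity, and the global metrics are
  computed on that connected graph (so Lp is always finite);
* the size of the largest connected component (LCC) is tracked on the
  INTACT network binarized at its own minimum connected density, with the
  removed nodes deleted — on the re-thresholded remaining graph the LCC
  would be trivially the whole graph.

Group comparison per removal step uses the same label-permutation machinery
as the rest of the pipeline: each permutation rebuilds both group networks,
regenerates the targeted orderings from the permuted groups' own BC (random
orderings are reused across permutations for variance reduction), reruns
the attacks, and records per-step metric differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from ._util import child_seed
from .metrics import (GLOBAL_METRICS, auc_over_grid, clustering_coefficient,
                      characteristic_path_length, distance_matrix,
                      global_efficiency, local_efficiency,
                      nodal_curves_from_stack, small_world)
from .network import (GroupNetwork, SparsityGrid, build_stack, default_grid,
                      min_density_connected)
from .permtest import _corr, _group_arrays, permutation_pvalue
from .suv_io import SUVTable

__all__ = [
    "AttackSchedule",
    "AttackResult",
    "RobustnessComparison",
    "targeted_schedule",
    "random_schedules",
    "run_attack",
    "compare_robustness",
    "largest_connected_component_size",
]

#: ceiling on n_perm x steps x reps x groups graph evaluations in
#: compare_robustness; a guard against accidentally huge runs
DEFAULT_MAX_EVALS = 5_000_000


def largest_connected_component_size(adj) -> int:
    """Node count of the largest connected component; 0 for an empty node
    set (singletons count as components of size 1)."""
    a = np.asarray(adj)
    if a.size == 0:
        return 0
    n_comp, labels = connected_components(a.astype(np.int8), directed=False)
    return int(np.bincount(labels).max())


@dataclass(frozen=True)
class AttackSchedule:
    """One or more full node-removal orderings.

    kind "targeted": a single static ordering by descending BC (AUC over the
    sparsity grid), ties broken by region index. kind "random": n_reps
    independent uniform permutations from seeded child streams.
    """

    kind: str
    orders: tuple[tuple[int, ...], ...]
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("random", "targeted"):
            raise ValueError(f"unknown attack kind {self.kind!r}")
        n = len(self.orders[0])
        for o in self.orders:
            if sorted(o) != list(range(n)):
                raise ValueError("each ordering must be a permutation of all nodes")


def targeted_schedule(net: GroupNetwork, grid: SparsityGrid | None = None,
                      ranking: str = "signed",
                      bc_auc: np.ndarray | None = None) -> AttackSchedule:
    """Static ordering of nodes by descending BC, where nodal BC is the AUC
    of the betweenness curve over the sparsity grid; ties by region index."""
    grid = grid or default_grid()
    if bc_auc is None:
        stack = build_stack(net, grid, ranking)
        bc_curves = nodal_curves_from_stack(stack, ("BC",))["BC"]
        bc_auc = np.array([auc_over_grid(bc_curves[:, v], grid)
                           for v in range(net.n_regions)])
    order = np.argsort(-np.asarray(bc_auc), kind="stable")
    return AttackSchedule(kind="targeted", orders=(tuple(int(v) for v in order),))


def random_schedules(n_nodes: int, n_reps: int = 40,
                     seed: int | None = None) -> AttackSchedule:
    """n_reps independent uniform node orderings from seeded child streams."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    orders = []
    for r in range(n_reps):
        rng = np.random.default_rng(child_seed(seed, "attack-order", r))
        orders.append(tuple(int(v) for v in rng.permutation(n_nodes)))
    return AttackSchedule(kind="random", orders=tuple(orders), seed=seed)


def _connected_metrics(net: GroupNetwork, surviving: np.ndarray, metrics,
                       ensemble_size: int, seed, ranking: str) -> dict:
    """Global metrics of the surviving subnetwork re-thresholded at minimum
    connected density."""
    _, adj = min_density_connected(net, surviving, ranking)
    out = {}
    need_dist = bool({"Lp", "Eglob"} & set(metrics))
    d = distance_matrix(adj) if need_dist else None
    if "Lp" in metrics:
        out["Lp"] = characteristic_path_length(adj, d)
    if "Eglob" in metrics:
        out["Eglob"] = global_efficiency(adj, d)
    if "Cp" in metrics:
        out["Cp"] = clustering_coefficient(adj)[1]
    if "Eloc" in metrics:
        out["Eloc"] = local_efficiency(adj)[1]
    if {"gamma", "lambda", "sigma"} & set(metrics):
        sw = small_world(adj, ensemble_size=ensemble_size, seed=seed)
        for name, v in (("gamma", sw.gamma), ("lambda", sw.lam), ("sigma", sw.sigma)):
            if name in metrics:
                out[name] = v
    return out


@dataclass
class AttackResult:
    """Per-step trajectories. ``steps`` counts removed nodes (0 = intact);
    metric and LCC values are averaged over orderings for the random kind."""

    kind: str
    steps: np.ndarray
    fractions: np.ndarray
    metrics_per_step: dict[str, np.ndarray]
    lcc_per_step: np.ndarray
    n_orders: int
    averaged: bool


def run_attack(net: GroupNetwork, schedule: AttackSchedule,
               grid: SparsityGrid | None = None,
               metrics=("Lp", "Cp", "Eglob", "Eloc", "sigma", "gamma", "lambda"),
               steps=None, ensemble_size: int = 100,
               seed: int | None = None, ranking: str = "signed") -> AttackResult:
    """Simulate the removal sequence(s) and track global metrics (on the
    min-density-connected remaining network) and LCC size (on the intact
    binary network with nodes deleted).

    ``steps`` is the list of removed-node counts to evaluate (default
    1..n-2, i.e. one node per step, ~1% of 96 per step); step 0 (intact)
    is always included first. For random schedules the trajectories are
    averaged over the orderings.
    """
    grid = grid or default_grid()
    metrics = tuple(metrics)
    unknown = set(metrics) - set(GLOBAL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    n = net.n_regions
    if steps is None:
        steps = list(range(1, n - 1))
    steps = [int(k) for k in steps]
    if any(k < 1 or k > n - 2 for k in steps):
        raise ValueError("steps must leave >= 2 surviving nodes")
    all_steps = np.array([0] + steps)

    # intact binary network at its own minimum connected density (for LCC)
    _, intact_adj = min_density_connected(net, np.arange(n), ranking)

    n_orders = len(schedule.orders)
    vals = {m: np.zeros((n_orders, len(all_steps))) for m in metrics}
    lcc = np.zeros((n_orders, len(all_steps)))
    base = _connected_metrics(net, np.arange(n), metrics, ensemble_size,
                              child_seed(seed, "step", 0) if seed is not None else None,
                              ranking)
    for oi, order in enumerate(schedule.orders):
        order = np.asarray(order)
        vals_0 = base
        lcc[oi, 0] = largest_connected_component_size(intact_adj)
        for m in metrics:
            vals[m][oi, 0] = vals_0[m]
        for si, k in enumerate(steps, start=1):
            surviving = np.setdiff1d(np.arange(n), order[:k])
            step_seed = (child_seed(seed, "step", oi, k)
                         if seed is not None else None)
            mv = _connected_metrics(net, surviving, metrics, ensemble_size,
                                    step_seed, ranking)
            for m in metrics:
                vals[m][oi, si] = mv[m]
            sub = intact_adj[np.ix_(surviving, surviving)]
            lcc[oi, si] = largest_connected_component_size(sub)
    averaged = schedule.kind == "random" and n_orders > 1
    return AttackResult(
        kind=schedule.kind, steps=all_steps,
        fractions=np.round(100 * all_steps / n).astype(int),
        metrics_per_step={m: vals[m].mean(0) for m in metrics},
        lcc_per_step=lcc.mean(0), n_orders=n_orders, averaged=averaged)


@dataclass
class RobustnessComparison:
    kind: str
    steps: np.ndarray
    metrics: tuple[str, ...]
    observed_diff: dict[str, np.ndarray]
    p_values: dict[str, np.ndarray]
    alpha: float
    significant_steps: dict[str, np.ndarray]
    n_perm: int
    seed: int | None
    groups: tuple[str, str] = ("", "")


def compare_robustness(table: SUVTable, kind: str,
                       grid: SparsityGrid | None = None,
                       n_perm: int = 1000, seed: int | None = None,
                       n_reps: int = 40, steps=None,
                       metrics=("Lp", "Cp", "Eglob", "Eloc"),
                       ensemble_size: int = 100, alpha: float = 0.05,
                       ranking: str = "signed",
                       max_evals: int = DEFAULT_MAX_EVALS) -> RobustnessComparison:
    """Per-step, per-metric permutation comparison of the two groups'
    attack trajectories.

    Targeted orderings are regenerated inside each permutation from the
    permuted group's own BC ranking; random orderings are reused across
    permutations (variance reduction). Refuses budgets whose projected
    graph-evaluation count exceeds ``max_evals``.
    """
    grid = grid or default_grid()
    metrics = tuple(metrics)
    x, mask_a, groups = _group_arrays(table)
    n_regions = x.shape[1]
    if steps is None:
        steps = list(range(1, n_regions - 1))
    steps = [int(k) for k in steps]
    n_orders = n_reps if kind == "random" else 1
    projected = (n_perm + 1) * (len(steps) + 1) * n_orders * 2
    if projected > max_evals:
        raise ValueError(
            f"projected {projected} graph evaluations exceed the ceiling "
            f"{max_evals}; lower n_perm, subsample steps, or reduce n_reps")
    if kind == "random":
        schedule = random_schedules(n_regions, n_reps, seed=child_seed(seed, "rand-sched"))
    elif kind != "targeted":
        raise ValueError(f"unknown attack kind {kind!r}")

    def group_trajectories(mask, perm_key):
        out = []
        for gi, part in enumerate((x[mask], x[~mask])):
            net = GroupNetwork(matrix=_corr(part), group_id=str(gi),
                               n_subjects=part.shape[0])
            sched = (schedule if kind == "random"
                     else targeted_schedule(net, grid, ranking))
            res = run_attack(net, sched, grid, metrics=metrics, steps=steps,
                             ensemble_size=ensemble_size,
                             seed=child_seed(seed, "attack", perm_key, gi)
                             if seed is not None else None,
                             ranking=ranking)
            out.append(res)
        return out

    res_a, res_b = group_trajectories(mask_a, "observed")
    observed = {m: res_a.metrics_per_step[m] - res_b.metrics_per_step[m]
                for m in metrics}
    rng = np.random.default_rng(child_seed(seed, "robustness-test", kind))
    n_steps = len(steps) + 1
    counts = {m: np.zeros(n_steps, dtype=np.int64) for m in metrics}
    for p_i in range(n_perm):
        pa, pb = group_trajectories(mask_a[rng.permutation(x.shape[0])], p_i)
        for m in metrics:
            null = pa.metrics_per_step[m] - pb.metrics_per_step[m]
            counts[m] += np.abs(null) >= np.abs(observed[m])
    p = {m: (1.0 + counts[m]) / (1.0 + n_perm) for m in metrics}
    sig = {m: res_a.steps[p[m] < alpha] for m in metrics}
    return RobustnessComparison(kind=kind, steps=res_a.steps, metrics=metrics,
                                observed_diff=observed, p_values=p, alpha=alpha,
                                significant_steps=sig, n_perm=n_perm, seed=seed,
                                groups=groups)
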