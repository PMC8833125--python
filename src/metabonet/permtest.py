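"""Nonparametric group comparison by subject-label permutation.

All between-group statistics (edge-wise correlation differences, global
metric AUCs over the sparsity grid, nodal metric AUCs) are compared against
a null distribution built by randomly reassigning subjects to two groups of
the original sizes and recomputing the full statistic pipeline — both
correlation matrices, both binary stacks, and the metric curves — in every
permutation cycle.

Two-tailed p-values use the add-one form p = (1 + #{|null| >= |obs|}) /
(1 + n_perm), which can never return 0 (minimum 1/(n_perm+1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._util import child_seed
from .metrics import (GLOBAL_METRICS, NODAL_METRICS, auc_over_grid,
                      global_curves_from_matrix, nodal_curves_from_matrix)
from .network import SparsityGrid, default_grid
from .suv_io import SUVTable

__all__ = [
    "PermutationResult",
    "EdgeTestResult",
    "NodalTestResult",
    "permutation_pvalue",
    "edge_permutation_test",
    "global_auc_permutation_test",
    "global_auc_permutation_test_multi",
    "nodal_auc_permutation_test",
    "bh_fdr",
]

DEFAULT_N_PERM = 5000


def permutation_pvalue(observed: float, null_samples) -> float:
    """Two-tailed add-one permutation p-value; never 0."""
    null = np.asarray(null_samples, dtype=float)
    if null.size < 1:
        raise ValueError("need at least one null sample")
    b = int(np.sum(np.abs(null) >= abs(observed)))
    return (1 + b) / (1 + null.size)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at FDR level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def _group_arrays(table: SUVTable):
    """Data in original row order plus the group-A membership mask. Group A
    is the first label in sorted order; observed statistics are A minus B.

    Permutations shuffle the MASK (not the rows), so relabeling the two
    groups exactly negates every observed and null difference and leaves
    every p-value unchanged.
    """
    labels = table.group_labels
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    ga, gb = labels
    mask_a = (table.groups == ga).to_numpy()
    if min(mask_a.sum(), (~mask_a).sum()) < 4:
        raise ValueError("need >= 4 subjects per group")
    return table.data.to_numpy(), mask_a, (ga, gb)


def _corr(x: np.ndarray) -> np.ndarray:
    m = np.corrcoef(x.T)
    m = np.clip(m, -1.0, 1.0)
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class PermutationResult:
    observed_diff: float
    null_diffs: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    statistic: str = ""
    groups: tuple[str, str] = ("", "")


@dataclass
class EdgeTestResult:
    """Edge-wise correlation-difference test. ``p_matrix`` diagonal is NaN;
    significant edge lists hold (i, j, observed_diff, p) tuples split by the
    sign of the observed difference (A - B) at the alpha threshold."""

    p_matrix: np.ndarray
    observed_diff: np.ndarray
    significant_increased: list
    significant_decreased: list
    alpha: float
    n_perm: int
    seed: int | None
    groups: tuple[str, str] = ("", "")
    region_names: tuple[str, ...] = ()


def edge_permutation_test(table: SUVTable, n_perm: int = DEFAULT_N_PERM,
                          seed: int | None = None,
                          alpha: float = 0.001) -> EdgeTestResult:
    """Per-edge two-tailed permutation test of the group difference in
    Pearson correlation, rebuilding BOTH correlation matrices per shuffle.
    """
    x, mask_a, groups = _group_arrays(table)
    n = x.shape[0]
    obs = _corr(x[mask_a]) - _corr(x[~mask_a])
    rng = np.random.default_rng(child_seed(seed, "edge-test"))
    counts = np.zeros_like(obs, dtype=np.int64)
    abs_obs = np.abs(obs)
    for _ in range(n_perm):
        pm = mask_a[rng.permutation(n)]
        null = _corr(x[pm]) - _corr(x[~pm])
        counts += np.abs(null) >= abs_obs
    p = (1.0 + counts) / (1.0 + n_perm)
    np.fill_diagonal(p, np.nan)
    iu, ju = np.triu_indices(n := obs.shape[0], 1)
    sig = p[iu, ju] < alpha
    inc, dec = [], []
    for i, j in zip(iu[sig], ju[sig]):
        rec = (int(i), int(j), float(obs[i, j]), float(p[i, j]))
        (inc if obs[i, j] > 0 else dec).append(rec)
    return EdgeTestResult(p_matrix=p, observed_diff=obs,
                          significant_increased=inc, significant_decreased=dec,
                          alpha=alpha, n_perm=n_perm, seed=seed, groups=groups,
                          region_names=tuple(table.data.columns))


def global_auc_permutation_test(table: SUVTable, metric: str,
                                grid: SparsityGrid | None = None,
                                n_perm: int = DEFAULT_N_PERM,
                                seed: int | None = None,
                                ensemble_size: int = 100,
                                ranking: str = "signed") -> PermutationResult:
    """Permutation test of the between-group difference in one global
    metric's AUC over the sparsity grid.

    Every permutation cycle rebuilds both group networks, stacks, metric
    curves and the AUC difference. gamma/lambda/sigma recompute the rewired
    ensemble inside every permutation at the (reduced, configurable)
    ``ensemble_size``.
    """
    return global_auc_permutation_test_multi(
        table, (metric,), grid, n_perm, seed, ensemble_size, ranking)[metric]


def global_auc_permutation_test_multi(table: SUVTable, metrics,
                                      grid: SparsityGrid | None = None,
                                      n_perm: int = DEFAULT_N_PERM,
                                      seed: int | None = None,
                                      ensemble_size: int = 100,
                                      ranking: str = "signed",
                                      ) -> dict[str, PermutationResult]:
    """As global_auc_permutation_test for several metrics in one shared
    permutation pass (gamma/lambda/sigma in particular reuse one rewired
    ensemble per layer instead of three)."""
    metrics = tuple(metrics)
    unknown = set(metrics) - set(GLOBAL_METRICS)
    if unknown:
        raise ValueError(f"unknown metric {sorted(unknown)}; choose from "
                         f"{GLOBAL_METRICS}")
    grid = grid or default_grid()
    x, mask_a, groups = _group_arrays(table)
    n = x.shape[0]
    key = "+".join(metrics)

    def auc_diffs(mask, perm_key) -> dict[str, float]:
        vals = []
        for gi, part in enumerate((x[mask], x[~mask])):
            curves = global_curves_from_matrix(
                _corr(part), grid, metrics, ranking, ensemble_size,
                seed=child_seed(seed, "global", key, perm_key, gi)
                if seed is not None else None)
            aucs = {}
            for m in metrics:
                bad = ~np.isfinite(curves[m])
                if bad.mean() > 0.2:
                    raise ValueError(
                        f"metric {m} undefined on {bad.sum()}/{len(grid)} grid "
                        f"points; cannot form a stable AUC")
                aucs[m] = auc_over_grid(curves[m], grid)
            vals.append(aucs)
        return {m: vals[0][m] - vals[1][m] for m in metrics}

    observed = auc_diffs(mask_a, "observed")
    rng = np.random.default_rng(child_seed(seed, "global-test", key))
    null = {m: np.empty(n_perm) for m in metrics}
    for p_i in range(n_perm):
        d = auc_diffs(mask_a[rng.permutation(n)], p_i)
        for m in metrics:
            null[m][p_i] = d[m]
    return {m: PermutationResult(
        observed_diff=observed[m], null_diffs=null[m],
        p_value=permutation_pvalue(observed[m], null[m]),
        n_perm=n_perm, seed=seed, statistic=f"AUC({m})", groups=groups)
        for m in metrics}


def _trapezoid_weights(grid: SparsityGrid) -> np.ndarray:
    s = grid.as_array()
    w = np.zeros_like(s)
    w[:-1] += np.diff(s) / 2
    w[1:] += np.diff(s) / 2
    return w


@dataclass
class NodalTestResult:
    """Per-region AUC permutation tests for the nodal metrics, with
    Benjamini-Hochberg FDR applied separately per metric across regions."""

    p_values: dict[str, np.ndarray]
    observed_diff: dict[str, np.ndarray]
    fdr_mask: dict[str, np.ndarray]
    q: float
    n_perm: int
    seed: int | None
    groups: tuple[str, str] = ("", "")
    region_names: tuple[str, ...] = ()


def nodal_auc_permutation_test(table: SUVTable,
                               grid: SparsityGrid | None = None,
                               n_perm: int = DEFAULT_N_PERM,
                               seed: int | None = None,
                               q: float = 0.05,
                               metrics=NODAL_METRICS,
                               ranking: str = "signed") -> NodalTestResult:
    """Per region and per nodal metric (D, BC, E_nod), permutation test of
    the AUC difference over the sparsity grid; BH-FDR per metric at level q.
    """
    metrics = tuple(metrics)
    grid = grid or default_grid()
    x, mask_a, groups = _group_arrays(table)
    n = x.shape[0]
    w = _trapezoid_weights(grid)

    def nodal_aucs(mask) -> dict[str, np.ndarray]:
        out = {}
        for part, key in ((x[mask], "a"), (x[~mask], "b")):
            curves = nodal_curves_from_matrix(_corr(part), grid, metrics, ranking)
            out[key] = {m: w @ curves[m] for m in metrics}
        return {m: out["a"][m] - out["b"][m] for m in metrics}

    observed = nodal_aucs(mask_a)
    rng = np.random.default_rng(child_seed(seed, "nodal-test"))
    counts = {m: np.zeros(x.shape[1], dtype=np.int64) for m in metrics}
    for _ in range(n_perm):
        null = nodal_aucs(mask_a[rng.permutation(n)])
        for m in metrics:
            counts[m] += np.abs(null[m]) >= np.abs(observed[m])
    p = {m: (1.0 + counts[m]) / (1.0 + n_perm) for m in metrics}
    masks = {m: bh_fdr(p[m], q) for m in metrics}
    return NodalTestResult(p_values=p, observed_diff=observed, fdr_mask=masks,
                           q=q, n_perm=n_perm, seed=seed, groups=groups,
                           region_names=tuple(table.data.columns))
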