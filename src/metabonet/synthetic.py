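"""Synthetic two-group SUV tables with controlled correlation structure.

The study design being emulated is a two-group cross-sectional PET cohort:
23 aged and 24 young subjects, 96 atlas regions each. Group-level metabolic
connectivity is the Pearson correlation of regional SUV across subjects, so
the generative model here is a per-group correlation matrix from which
subject rows are drawn as independent multivariate normals. Pearson
correlation is location/scale invariant, so the Gaussian marginal (shifted
to a realistic SUV scale) is immaterial to everything downstream.

The base correlation matrix is block-structured (communities with a common
within-community correlation and a weaker between-community correlation),
onto which edge-level group differences and hub perturbations are planted
by overwriting individual entries, followed by a projection back to the
positive-semidefinite cone (eigenvalue clipping + unit-diagonal rescaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import child_seed
from .suv_io import SUVTable

__all__ = [
    "SyntheticSpec",
    "GroupCovariance",
    "build_group_covariance",
    "sample_suv_table",
    "make_dataset",
    "make_null_dataset",
    "default_study_spec",
    "plant_hub",
]

#: entry distortion beyond which a planted request is declared non-realizable
MAX_PLANTED_DISTORTION = 0.1


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic two-group cohort.

    planted_edges entries are (i, j, r_group_a, r_group_b) with 0-based
    region indices; they overwrite the block-structure base correlation.
    """

    n_regions: int = 96
    n_per_group: tuple[int, int] = (23, 24)
    community_sizes: tuple[int, ...] = (24, 24, 24, 24)
    within_r: float = 0.5
    between_r: float = 0.1
    planted_edges: tuple[tuple[int, int, float, float], ...] = ()
    suv_mean: float = 1.0
    suv_sd: float = 0.15
    group_labels: tuple[str, str] = ("aged", "young")

    def __post_init__(self):
        if sum(self.community_sizes) != self.n_regions:
            raise ValueError("community sizes must sum to n_regions")
        if min(self.n_per_group) < 4:
            raise ValueError("need >= 4 subjects per group (Pearson r needs >= 3 df)")
        for r in (self.within_r, self.between_r):
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"base correlation {r} outside [-1, 1]")
        seen = set()
        for (i, j, ra, rb) in self.planted_edges:
            if i == j:
                raise ValueError(f"planted edge ({i},{j}) is a self-pair")
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                raise ValueError(f"planted edge ({i},{j}) out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"planted pair {key} listed twice")
            seen.add(key)
            for r in (ra, rb):
                if not -1.0 <= r <= 1.0:
                    raise ValueError(f"planted correlation {r} outside [-1, 1]")
        if not (self.suv_mean > 0 and self.suv_sd > 0):
            raise ValueError("suv_mean and suv_sd must be positive")


@dataclass(frozen=True)
class GroupCovariance:
    """One group's generating correlation matrix (symmetric, unit diagonal,
    PSD after repair). ``max_distortion`` is max |requested - realized| over
    the explicitly requested (block + planted) entries."""

    matrix: np.ndarray
    group_id: str
    max_distortion: float = 0.0

    def __post_init__(self):
        m = self.matrix
        if not np.allclose(m, m.T):
            raise ValueError("covariance must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("covariance must have unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValueError("covariance must be positive semidefinite")


def _base_matrix(spec: SyntheticSpec) -> np.ndarray:
    n = spec.n_regions
    m = np.full((n, n), spec.between_r, dtype=float)
    start = 0
    for size in spec.community_sizes:
        m[start : start + size, start : start + size] = spec.within_r
        start += size
    np.fill_diagonal(m, 1.0)
    return m


def _nearest_psd_correlation(m: np.ndarray, max_iter: int = 200,
                             tol: float = 1e-10) -> np.ndarray:
    """Nearest correlation matrix by alternating projections with Dykstra
    correction: eigenvalue clipping at 0 (projection onto the PSD cone)
    alternated with restoring the unit diagonal, keeping the result as
    close to the request (Frobenius) as the two constraints allow."""
    x = m.copy()
    ds = np.zeros_like(m)
    for _ in range(max_iter):
        r = x - ds
        w, v = np.linalg.eigh(r)
        x_psd = (v * np.clip(w, 0, None)) @ v.T
        x_psd = (x_psd + x_psd.T) / 2
        ds = x_psd - r
        x_prev = x
        x = x_psd.copy()
        np.fill_diagonal(x, 1.0)
        if (np.abs(x - x_prev).max() < tol
                and np.linalg.eigvalsh(x).min() >= -tol):
            break
    # final safeguard: one plain clip + diagonal rescale if still indefinite
    w, v = np.linalg.eigh(x)
    if w.min() < -tol:
        x = (v * np.clip(w, 0, None)) @ v.T
        d = np.sqrt(np.clip(np.diag(x), 1e-12, None))
        x = x / np.outer(d, d)
        x = (x + x.T) / 2
        np.fill_diagonal(x, 1.0)
    return x


def build_group_covariance(spec: SyntheticSpec, group_id: str) -> GroupCovariance:
    """Realize the block structure with this group's planted entries, then
    repair to the nearest PSD correlation matrix.

    Raises if the repair moves any planted entry by more than
    MAX_PLANTED_DISTORTION (the request is declared non-realizable).
    """
    idx = {spec.group_labels[0]: 2, spec.group_labels[1]: 3}
    if group_id not in idx:
        raise KeyError(f"unknown group {group_id!r}; spec has {spec.group_labels}")
    requested = _base_matrix(spec)
    for edge in spec.planted_edges:
        i, j = edge[0], edge[1]
        r = edge[idx[group_id]]
        requested[i, j] = requested[j, i] = r
    repaired = _nearest_psd_correlation(requested)
    offenders = []
    for edge in spec.planted_edges:
        i, j = edge[0], edge[1]
        d = abs(requested[i, j] - repaired[i, j])
        if d > MAX_PLANTED_DISTORTION:
            offenders.append((i, j, float(d)))
    if offenders:
        raise ValueError(
            f"non-realizable covariance for group {group_id!r}: PSD repair moved "
            f"planted entries (i, j, |delta|) = {offenders}"
        )
    max_dist = float(np.abs(requested - repaired).max())
    return GroupCovariance(matrix=repaired, group_id=group_id, max_distortion=max_dist)


def _sample_group(cov: GroupCovariance, n: int, mean: float, sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    # eigh factor rather than Cholesky: repaired matrices may be singular-PSD
    w, v = np.linalg.eigh(cov.matrix)
    factor = v * np.sqrt(np.clip(w, 0, None))
    z = rng.standard_normal((n, cov.matrix.shape[0]))
    return z @ factor.T * sd + mean


def sample_suv_table(cov_a: GroupCovariance, cov_b: GroupCovariance,
                     n_a: int, n_b: int, suv_mean: float, suv_sd: float,
                     seed: int, region_names: list[str] | None = None,
                     group_labels: tuple[str, str] | None = None) -> SUVTable:
    """Draw the two groups' subject rows and assemble a labeled SUV table.

    Same seed -> bit-identical table. A seed is mandatory.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if min(n_a, n_b) < 4:
        raise ValueError("need >= 4 subjects per group")
    n_regions = cov_a.matrix.shape[0]
    if cov_b.matrix.shape[0] != n_regions:
        raise ValueError("group covariances must have the same dimension")
    labels = group_labels or (cov_a.group_id, cov_b.group_id)
    if labels[0] == labels[1]:
        raise ValueError("the two groups must carry distinct labels")
    rng_a = np.random.default_rng(child_seed(seed, "sample", labels[0]))
    rng_b = np.random.default_rng(child_seed(seed, "sample", labels[1]))
    xa = _sample_group(cov_a, n_a, suv_mean, suv_sd, rng_a)
    xb = _sample_group(cov_b, n_b, suv_mean, suv_sd, rng_b)
    if region_names is None:
        region_names = [f"R{k+1:03d}" for k in range(n_regions)]
    subjects = [f"{labels[0]}_{k+1:02d}" for k in range(n_a)] + \
               [f"{labels[1]}_{k+1:02d}" for k in range(n_b)]
    data = pd.DataFrame(np.vstack([xa, xb]), index=pd.Index(subjects, name="subject"),
                        columns=region_names)
    groups = pd.Series([labels[0]] * n_a + [labels[1]] * n_b, index=data.index,
                       name="group")
    return SUVTable(data=data, groups=groups, normalized=False)


def make_dataset(spec: SyntheticSpec, seed: int,
                 region_names: list[str] | None = None) -> SUVTable:
    """Build both group covariances from the spec and sample a table."""
    cov_a = build_group_covariance(spec, spec.group_labels[0])
    cov_b = build_group_covariance(spec, spec.group_labels[1])
    return sample_suv_table(cov_a, cov_b, *spec.n_per_group, spec.suv_mean,
                            spec.suv_sd, seed, region_names=region_names,
                            group_labels=spec.group_labels)


def make_null_dataset(spec: SyntheticSpec, seed: int,
                      region_names: list[str] | None = None) -> SUVTable:
    """Both groups drawn from the SAME covariance (group A's planted values
    applied to both, so planted edges carry no group difference). Used to
    calibrate permutation-test false-positive rates."""
    if spec.planted_edges:
        warnings.warn("null dataset: planted group differences ignored "
                      "(group A values applied to both groups)")
    cov = build_group_covariance(spec, spec.group_labels[0])
    cov_b = GroupCovariance(matrix=cov.matrix, group_id=spec.group_labels[1],
                            max_distortion=cov.max_distortion)
    return sample_suv_table(cov, cov_b, *spec.n_per_group, spec.suv_mean,
                            spec.suv_sd, seed, region_names=region_names,
                            group_labels=spec.group_labels)


def default_study_spec(planted: bool = True) -> SyntheticSpec:
    """The default synthetic cohort: 96 regions in 4 communities of 24
    (within-community r = 0.5, between 0.1), 23 + 24 subjects.

    With ``planted=True``, eight within-community edge-level differences at
    the default detectable-regime magnitude (r = 0.8 vs 0.0: four increased,
    four decreased in group A) plus a hub perturbation (region 12's
    correlations to 20 community-2 partners raised from the 0.1 baseline to
    0.45 in group A only). Effects are planted within or adjacent to the
    community structure so the requested matrices stay (near-)PSD; strong
    correlations between members of otherwise weakly-coupled communities are
    geometrically infeasible for a correlation matrix and would be distorted
    by the PSD repair.
    """
    if not planted:
        return SyntheticSpec()
    edges = [
        # (i, j, r_aged, r_young): increased in aged
        (0, 5, 0.8, 0.0), (2, 9, 0.8, 0.0), (26, 30, 0.8, 0.0), (52, 60, 0.8, 0.0),
        # decreased in aged
        (28, 40, 0.0, 0.8), (50, 55, 0.0, 0.8), (75, 80, 0.0, 0.8), (77, 90, 0.0, 0.8),
    ]
    spec = SyntheticSpec(planted_edges=tuple(edges))
    return plant_hub(spec, region=12, partners=tuple(range(26, 46)),
                     r_hub=0.45, group="a")


def plant_hub(spec: SyntheticSpec, region: int, partners: tuple[int, ...],
              r_hub: float, group: str = "a") -> SyntheticSpec:
    """Add planted edges raising one region's correlations to a set of
    partners in one group only (the other group keeps the base value).
    Returns a new spec."""
    base = _base_matrix(spec)
    new_edges = list(spec.planted_edges)
    existing = {(min(i, j), max(i, j)) for i, j, *_ in new_edges}
    for p in partners:
        key = (min(region, p), max(region, p))
        if key in existing:
            raise ValueError(f"hub partner pair {key} already planted")
        other = base[region, p]
        if group == "a":
            new_edges.append((region, p, r_hub, other))
        else:
            new_edges.append((region, p, other, r_hub))
    return SyntheticSpec(
        n_regions=spec.n_regions, n_per_group=spec.n_per_group,
        community_sizes=spec.community_sizes, within_r=spec.within_r,
        between_r=spec.between_r, planted_edges=tuple(new_edges),
        suv_mean=spec.suv_mean, suv_sd=spec.suv_sd,
        group_labels=spec.group_labels,
    )
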