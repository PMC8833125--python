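"""Shared helpers: seed derivation, deterministic rounding, union-find."""

from __future__ import annotations

import numpy as np

# Cap child seeds below 2**31 so they survive round-trips through JSON,
# R, and signed-int config fields.
_SEED_MOD = 2**31 - 1


def child_seed(seed: int, *key: object) -> int:
    """Derive a named child seed from a master seed.

    Stream splitting is by name, not by draw order, so each pipeline stage
    is independently reproducible: ``child_seed(master, "edge-test")`` does
    not change when an upstream stage adds or removes random draws.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    ss = np.random.SeedSequence([int(seed) % _SEED_MOD] + [_hash_key(k) for k in key])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % _SEED_MOD


def _hash_key(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) % _SEED_MOD
    # stable string hash (FNV-1a), independent of PYTHONHASHSEED
    h = 2166136261
    for b in str(key).encode():
        h = ((h ^ b) * 16777619) & 0xFFFFFFFF
    return h % _SEED_MOD


def round_half_away(x: float) -> int:
    """round() with halves away from zero, platform-independent.

    Used for edge counts k = round(S * n_pairs) so that every
    implementation agrees on the retained edge count.
    """
    return int(np.floor(abs(x) + 0.5) * np.sign(x))


class UnionFind:
    """Disjoint-set forest with path halving; used by the minimum-density
    connected thresholding and its oracle."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.n_components = n

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        self.n_components -= 1
        return True
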