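"""Bipartition enumeration for the minimum-information-partition search.

A system of ``n`` channels has ``2**(n-1) - 1`` distinct unordered
bipartitions into two nonempty parts.  The field's customary enumeration
formula ``sum_{k=1..n//2} C(n, k)`` counts balanced splits of even ``n``
twice (162 for n=8 instead of 127); both counts are exposed — the raw
formula for bookkeeping against the literature, the distinct enumeration
for the actual search (the argmin is unaffected by double counting).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np

__all__ = [
    "Bipartition", "enumerate_bipartitions", "raw_bipartition_count",
    "distinct_bipartition_count",
]


@dataclass(frozen=True)
class Bipartition:
    """Two disjoint nonempty index sets covering a channel unit.

    Canonical form: ``part1`` is the part containing the smallest index
    (hence the lexicographically smaller set).
    """

    part1: tuple[int, ...]
    part2: tuple[int, ...]

    def __post_init__(self):
        if not self.part1 or not self.part2:
            raise ValueError("both parts must be nonempty")
        if set(self.part1) & set(self.part2):
            raise ValueError("parts must be disjoint")
        if min(self.part1) > min(self.part2):
            raise ValueError("canonical form requires part1 to contain the smallest index")

    def __str__(self):
        return f"{{{','.join(map(str, self.part1))}}}|{{{','.join(map(str, self.part2))}}}"


def raw_bipartition_count(n: int) -> int:
    """``sum_{k=1..n//2} C(n, k)`` — the customary printed count (162 for n=8)."""
    return sum(comb(n, k) for k in range(1, n // 2 + 1))


def distinct_bipartition_count(n: int) -> int:
    """Number of distinct unordered bipartitions: ``2**(n-1) - 1``."""
    return 2 ** (n - 1) - 1


@lru_cache(maxsize=None)
def enumerate_bipartitions(n: int) -> tuple[Bipartition, ...]:
    """All distinct bipartitions of ``range(n)`` in canonical, deterministic order.

    Part 1 always contains index 0; partitions are ordered by the bitmask of
    part 1's remaining members, which makes ties in the MIP search break
    deterministically.
    """
    if not 2 <= n <= 16:
        raise ValueError(f"bipartition enumeration supports 2 <= n <= 16, got {n}")
    out = []
    for mask in range(2 ** (n - 1) - 1):  # subsets of {1..n-1}, excluding all
        p1 = (0,) + tuple(i for i in range(1, n) if mask >> (i - 1) & 1)
        p2 = tuple(i for i in range(1, n) if not mask >> (i - 1) & 1)
        out.append(Bipartition(p1, p2))
    return tuple(out)


@lru_cache(maxsize=None)
def _partition_tables(n: int):
    """Index tables used by the vectorized subset-log-det kernel.

    Returns (subsets_by_size, pair_bits, full_bits, norm_factor) where
    subsets_by_size maps size s -> (members (m, s), bitmask ids (m,)),
    pair_bits is an (n_partitions, 2) array of part bitmasks in canonical
    enumeration order, and norm_factor[p] = min(|part1|, |part2|).
    """
    parts = enumerate_bipartitions(n)

    def bits(t):
        b = 0
        for i in t:
            b |= 1 << i
        return b

    pair_bits = np.array([[bits(p.part1), bits(p.part2)] for p in parts], dtype=np.int64)
    norm = np.array([min(len(p.part1), len(p.part2)) for p in parts], dtype=np.float64)
    subsets: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    by_size: dict[int, list[tuple[int, ...]]] = {s: [] for s in range(1, n + 1)}
    for m in range(1, 2 ** n):
        members = tuple(i for i in range(n) if m >> i & 1)
        by_size[len(members)].append(members)
    for s, mem in by_size.items():
        arr = np.array(mem, dtype=np.int64)
        ids = np.array([bits(t) for t in mem], dtype=np.int64)
        subsets[s] = (arr, ids)
    return subsets, pair_bits, 2 ** n - 1, norm
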