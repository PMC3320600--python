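"""Independent brute-force oracles used by the tests.

Each function re-derives a statistic from its definition with no shared
code path into the package implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def brute_force_pairs(records, window: int) -> int:
    """O(n^2) enumeration of clustered pairs from the gap definition."""
    n = len(records)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            if a.chrom != b.chrom:
                continue
            if a.start <= b.start:
                gap = b.start - a.end - 1
            else:
                gap = a.start - b.end - 1
            if max(0, gap) <= window:
                count += 1
    return count


def brute_force_pairs_np(records, window: int) -> int:
    """O(n^2) enumeration via a full pairwise matrix (no sorting, no sweep)."""
    n = len(records)
    if n < 2:
        return 0
    chroms = np.array([r.chrom for r in records], dtype=object)
    starts = np.array([r.start for r in records], dtype=np.int64)
    ends = np.array([r.end for r in records], dtype=np.int64)
    same_chrom = chroms[:, None] == chroms[None, :]
    # gap(i, j) from the definition: later start minus earlier end minus 1
    i_earlier = starts[:, None] <= starts[None, :]
    gap_ij = starts[None, :] - ends[:, None] - 1    # valid where i is earlier
    gap_ji = starts[:, None] - ends[None, :] - 1
    gap = np.where(i_earlier, gap_ij, gap_ji)
    clustered = same_chrom & (np.maximum(gap, 0) <= window)
    np.fill_diagonal(clustered, False)
    return int(clustered.sum()) // 2


def brute_force_clustered_genes(records, window: int) -> int:
    """Genes participating in at least one clustered pair, by enumeration."""
    n = len(records)
    clustered = set()
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            if a.chrom != b.chrom:
                continue
            gap = (b.start - a.end - 1) if a.start <= b.start \
                else (a.start - b.end - 1)
            if max(0, gap) <= window:
                clustered.update((i, j))
    return len(clustered)


def brute_force_components(records, window: int):
    """Connected components (size >= 2) via union-find over all pairs."""
    n = len(records)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            if a.chrom != b.chrom:
                continue
            gap = (b.start - a.end - 1) if a.start <= b.start \
                else (a.start - b.end - 1)
            if max(0, gap) <= window:
                parent[find(i)] = find(j)
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(records[i].gene_id)
    return sorted((frozenset(g) for g in groups.values() if len(g) >= 2),
                  key=lambda s: sorted(s))


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH from the definition: adj_(i) = min_{j>=i} m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = math.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, m * p[idx] / rank)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def exact_hypergeom_upper_tail(universe_n: int, n_draws: int, n_marked: int,
                               k: int) -> float:
    """Exact tail P(X >= k) by rational enumeration of the pmf."""
    total = Fraction(0)
    denom = math.comb(universe_n, n_draws)
    for i in range(k, min(n_draws, n_marked) + 1):
        if n_draws - i > universe_n - n_marked:
            continue
        total += Fraction(
            math.comb(n_marked, i) * math.comb(universe_n - n_marked,
                                               n_draws - i), denom)
    return float(total)
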