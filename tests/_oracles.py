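"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_upper_tail_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P[X >= k] for X ~ Hypergeom(N, K, n), exact rational enumeration."""
    denom = comb(N, n)
    num = 0
    for x in range(max(k, 0), min(K, n) + 1):
        if n - x <= N - K:
            num += comb(K, x) * comb(N - K, n - x)
    return Fraction(num, denom)


def paint(intervals, size: int) -> np.ndarray:
    """Per-base bitmap of a list of (start, end) pairs on one toy chromosome."""
    bm = np.zeros(size, dtype=bool)
    for s, e in intervals:
        bm[s:e] = True
    return bm


def runs(bitmap: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of set bits as half-open (start, end) pairs."""
    out = []
    idx = np.flatnonzero(bitmap)
    if idx.size == 0:
        return out
    start = prev = int(idx[0])
    for i in idx[1:]:
        if i != prev + 1:
            out.append((start, prev + 1))
            start = int(i)
        prev = int(i)
    out.append((start, prev + 1))
    return out


def merge_oracle(intervals, max_gap: int, size: int) -> list[tuple[int, int]]:
    """Bitmap merge: paint, then repeatedly bridge gaps strictly below
    max_gap between adjacent runs until stable."""
    bm = paint(intervals, size)
    while True:
        rs = runs(bm)
        changed = False
        for (s1, e1), (s2, e2) in zip(rs, rs[1:]):
            if s2 - e1 < max_gap:
                bm[e1:s2] = True
                changed = True
        if not changed:
            return runs(bm)


def intersect_filter_oracle(stretches, marks, min_overlap: int, size: int):
    """Keep stretches whose painted overlap with the marks bitmap is >= min_overlap."""
    mark_bm = paint(marks, size)
    return [(s, e) for s, e in stretches if int(mark_bm[s:e].sum()) >= min_overlap]


def annotate_oracle(positions_1based, intervals) -> np.ndarray:
    """Per-SNP membership by linear scan over all intervals."""
    out = np.zeros(len(positions_1based), dtype=bool)
    for i, p in enumerate(positions_1based):
        for s, e in intervals:
            if s <= p - 1 < e:
                out[i] = True
                break
    return out


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def ld_blocks_oracle(chroms, positions, r2, window: int, r2_min: float) -> np.ndarray:
    """Union-find over all pairs; returns dense block labels in panel order."""
    n = len(positions)
    uf = UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if (
                chroms[i] == chroms[j]
                and abs(int(positions[j]) - int(positions[i])) < window
                and r2[i, j] >= r2_min
            ):
                uf.union(i, j)
    labels = {}
    out = np.empty(n, dtype=int)
    for i in range(n):
        r = uf.find(i)
        out[i] = labels.setdefault(r, len(labels))
    return out
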