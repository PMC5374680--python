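"""Random LD pruning: one representative per 1-Mb LD block, iterated.

SNP enrichment tests assume independent markers; LD violates that. Pruning
keeps a single randomly chosen representative of each LD block — the
connected components of the graph joining same-chromosome SNP pairs that lie
within a distance window (default 1 Mb) at pairwise r² >= 0.2 — and the whole
draw-then-test procedure is repeated (default 100 times) with the downstream
statistic averaged, which removes the arbitrariness of any single draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .gwas import SnpPanel

__all__ = [
    "LdBlockAssignment",
    "PrunedStatistic",
    "build_ld_blocks",
    "random_prune",
    "prune_and_average",
    "child_rng",
]

DEFAULT_WINDOW = 1_000_000
DEFAULT_R2 = 0.2
DEFAULT_ITERATIONS = 100


@dataclass
class LdBlockAssignment:
    """Panel-aligned block ids; SNPs sharing an id form one LD block."""

    block_id: np.ndarray
    window_size: int = DEFAULT_WINDOW
    r2_threshold: float = DEFAULT_R2
    mode: str = "components"

    @property
    def n_blocks(self) -> int:
        return int(self.block_id.max()) + 1 if self.block_id.size else 0

    def block_sizes(self) -> np.ndarray:
        return np.bincount(self.block_id, minlength=self.n_blocks)


@dataclass
class PrunedStatistic:
    """Per-iteration values of a statistic over random prunes, with summary."""

    statistic_name: str
    values: np.ndarray  # NaN marks a failed iteration
    seed: int
    n_iter: int = field(init=False)
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_iter = len(self.values)
        done = self.values[~np.isnan(self.values)]
        if done.size == 0:
            self.mean = self.sd = float("nan")
        elif np.all(done == done[0]):
            # constant statistic: exactly zero spread, no summation rounding
            self.mean, self.sd = float(done[0]), 0.0
        else:
            self.mean = float(done.mean())
            self.sd = float(done.std(ddof=0))


def build_ld_blocks(
    panel: SnpPanel,
    ld,
    window_size: int = DEFAULT_WINDOW,
    r2_threshold: float = DEFAULT_R2,
    mode: Literal["components", "greedy"] = "components",
) -> LdBlockAssignment:
    """Partition the panel into LD blocks.

    ``components`` (default): blocks are the connected components of the
    thresholded r² graph restricted to same-chromosome pairs closer than
    ``window_size`` — transitive chaining, so no retained pair within a block
    violates the threshold, though a chained block may span more than the
    window. ``greedy``: left-to-right clumping that also caps each block's
    span at the window (comparison mode). Singletons form their own blocks.
    """
    n = len(panel)
    edge_list = list(ld.edges(panel, window_size, r2_threshold))
    if mode == "components":
        if edge_list:
            ii = np.fromiter((e[0] for e in edge_list), int, len(edge_list))
            jj = np.fromiter((e[1] for e in edge_list), int, len(edge_list))
            adj = sp.coo_matrix(
                (np.ones(len(ii)), (ii, jj)), shape=(n, n)
            )
            _, labels = connected_components(adj, directed=False)
        else:
            labels = np.arange(n)
    elif mode == "greedy":
        # seed a clump at each unassigned SNP in panel order; absorb later
        # edge partners that stay within the window of the clump seed
        labels = np.full(n, -1, dtype=int)
        partners: dict[int, list[int]] = {}
        for i, j, _ in edge_list:
            partners.setdefault(i, []).append(j)
            partners.setdefault(j, []).append(i)
        pos = panel.positions
        nxt = 0
        for i in range(n):
            if labels[i] >= 0:
                continue
            labels[i] = nxt
            for j in sorted(partners.get(i, [])):
                if labels[j] < 0 and abs(int(pos[j]) - int(pos[i])) < window_size:
                    labels[j] = nxt
            nxt += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    # relabel densely in panel order for stable block ids
    order = {}
    dense = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        dense[i] = order.setdefault(lab, len(order))
    return LdBlockAssignment(dense, window_size, r2_threshold, mode)


def child_rng(master_seed: int, iteration: int) -> np.random.Generator:
    """Counter-based child stream: iteration k reproducible in isolation."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(iteration,))
    )


def random_prune(
    assignment: LdBlockAssignment, seed: int | np.random.Generator
) -> np.ndarray:
    """Uniformly choose one panel index per block; deterministic given seed.

    Returns the chosen indices sorted ascending.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bid = assignment.block_id
    n = len(bid)
    # random priority per SNP; representative = argmax priority within block
    priority = rng.random(n)
    chosen = np.full(assignment.n_blocks, -1, dtype=int)
    best = np.full(assignment.n_blocks, -1.0)
    for i in range(n):
        b = bid[i]
        if priority[i] > best[b]:
            best[b] = priority[i]
            chosen[b] = i
    return np.sort(chosen)


def prune_and_average(
    panel: SnpPanel,
    assignment: LdBlockAssignment,
    stat_fn: Callable[[np.ndarray], float],
    n_iter: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    statistic_name: str = "statistic",
) -> PrunedStatistic:
    """Run ``stat_fn(pruned_indices)`` on ``n_iter`` independent random
    prunes and average.

    ``stat_fn`` receives the sorted panel indices retained in one draw and
    returns a scalar (e.g. a Fisher p-value on the pruned panel). Failed
    iterations are recorded as NaN and excluded from the mean; more than 50%
    failures is an error.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(assignment.block_id) != len(panel):
        raise ValueError("assignment does not cover the panel")
    values = np.full(n_iter, np.nan)
    for it in range(n_iter):
        idx = random_prune(assignment, child_rng(seed, it))
        try:
            values[it] = float(stat_fn(idx))
        except Exception:  # noqa: BLE001 - failures recorded, not fatal
            pass
    n_fail = int(np.isnan(values).sum())
    if n_fail * 2 > n_iter:
        raise RuntimeError(
            f"{n_fail}/{n_iter} pruning iterations failed; statistic unusable"
        )
    return PrunedStatistic(statistic_name, values, seed=seed)
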