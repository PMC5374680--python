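"""Pairwise-LD (r²) sources.

Two interchangeable backends feed the pruning and matching stages:

* a genotype dosage matrix (SNPs x samples; dosages 0/1/2), from which r² is
  the squared Pearson correlation of dosage vectors;
* a precomputed sparse table of (snp_id_a, snp_id_b, r2) pairs.

Either way the consumer sees one interface: ``edges(panel, window, r2_min)``
yields the same-chromosome SNP index pairs closer than ``window`` bases whose
r² meets the threshold.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["GenotypeLd", "SparseLd", "load_ld", "r2_matrix"]


def r2_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between all rows of a dosage matrix.

    Monomorphic SNPs (zero variance) get r² = 0 against every partner.
    """
    g = np.asarray(genotypes, dtype=float)
    g = g - g.mean(axis=1, keepdims=True)
    sd = np.sqrt((g**2).sum(axis=1))
    ok = sd > 0
    gn = np.zeros_like(g)
    gn[ok] = g[ok] / sd[ok, None]
    r = gn @ gn.T
    np.fill_diagonal(r, 1.0)
    r2 = r**2
    r2[~ok, :] = 0.0
    r2[:, ~ok] = 0.0
    return np.clip(r2, 0.0, 1.0)


class GenotypeLd:
    """r² computed on demand from a dosage matrix aligned to a panel."""

    def __init__(self, genotypes: np.ndarray):
        self.genotypes = np.asarray(genotypes)

    def edges(
        self, panel, window: int, r2_min: float
    ) -> Iterator[tuple[int, int, float]]:
        """Yield (i, j, r²) for same-chromosome pairs with distance < window
        and r² >= r2_min. Banded: correlations are taken offset by offset, so
        cost scales with the neighbour count inside the window, not n²."""
        if not (0 <= r2_min <= 1):
            raise ValueError("r2 threshold must lie in [0, 1]")
        chroms = panel.chroms
        pos = panel.positions
        g = self.genotypes.astype(float)
        g = g - g.mean(axis=1, keepdims=True)
        sd = np.sqrt((g**2).sum(axis=1))
        ok = sd > 0
        gn = np.zeros_like(g)
        gn[ok] = g[ok] / sd[ok, None]
        n = len(pos)
        for d in range(1, n):
            i = np.arange(0, n - d)
            j = i + d
            near = (chroms[i] == chroms[j]) & (np.abs(pos[j] - pos[i]) < window)
            if not near.any():
                # panel is position-sorted per chromosome: larger offsets only
                # move further away, but chromosomes interleave in index space,
                # so stop only when no pair at this offset shares a chromosome
                if not (chroms[i] == chroms[j]).any():
                    break
                continue
            ii, jj = i[near], j[near]
            r2 = (gn[ii] * gn[jj]).sum(axis=1) ** 2
            hit = r2 >= r2_min
            for a, b, v in zip(ii[hit], jj[hit], r2[hit]):
                yield int(a), int(b), float(v)


class SparseLd:
    """Precomputed sparse r² pairs keyed by snp_id."""

    def __init__(self, pairs: pd.DataFrame):
        required = {"snp_id_a", "snp_id_b", "r2"}
        if not required <= set(pairs.columns):
            raise ValueError(f"sparse LD table needs columns {sorted(required)}")
        r2 = pairs["r2"].to_numpy(dtype=float)
        if ((r2 < 0) | (r2 > 1)).any():
            raise ValueError("r2 values outside [0, 1]")
        self.pairs = pairs

    def edges(
        self, panel, window: int, r2_min: float
    ) -> Iterator[tuple[int, int, float]]:
        if not (0 <= r2_min <= 1):
            raise ValueError("r2 threshold must lie in [0, 1]")
        idx = {s: i for i, s in enumerate(panel.df["snp_id"])}
        chroms = panel.chroms
        pos = panel.positions
        for a, b, v in self.pairs[["snp_id_a", "snp_id_b", "r2"]].itertuples(index=False):
            if v < r2_min or a not in idx or b not in idx:
                continue
            i, j = idx[a], idx[b]
            if i == j or chroms[i] != chroms[j]:
                continue
            if abs(int(pos[i]) - int(pos[j])) >= window:
                continue
            yield (i, j, float(v)) if i < j else (j, i, float(v))


def load_ld(path: str | Path, kind: str | None = None):
    """Load an LD source from disk.

    ``kind='genotypes'``: TSV with snp_id then one dosage column per sample.
    ``kind='sparse'``: 3-column TSV (snp_id_a, snp_id_b, r2). Inferred from
    the header when not given.
    """
    df = pd.read_csv(path, sep="\t")
    if kind is None:
        kind = "sparse" if {"snp_id_a", "snp_id_b", "r2"} <= set(df.columns) else "genotypes"
    if kind == "sparse":
        return SparseLd(df)
    if kind == "genotypes":
        dosages = df.drop(columns=["snp_id"], errors="ignore")
        return GenotypeLd(dosages.to_numpy(dtype=np.int8))
    raise ValueError(f"unknown LD source kind {kind!r}")
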