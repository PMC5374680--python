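"""MAF/LD-matched control SNP sets.

Enrichment inside enhancers could in principle reflect nothing more than the
allele-frequency spectrum or LD density of enhancer-resident SNPs. The
matched-control background rules this out: for each annotation SNP (case) we
draw non-annotation SNPs from the same joint (MAF, LD) bin, where the LD
coordinate is the SNP's LD-partner count — the number of same-chromosome
partners within 1 Mb at r² >= 0.2, an LD-score-like scalar standing in for
the underdetermined notion of matching "mutual LD r²" pairwise structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import AnnotationMask, SnpPanel
from .pruning import DEFAULT_R2, DEFAULT_WINDOW

logger = logging.getLogger(__name__)

__all__ = ["MatchSpec", "MatchResult", "ld_partner_count", "match_controls"]


@dataclass
class MatchSpec:
    """Binning and sampling parameters for control matching.

    ``maf_bin_edges``/``ld_bin_edges`` of None defer to data-driven defaults:
    MAF deciles and LD-partner-count quartiles of the case set.
    """

    maf_bin_edges: np.ndarray | None = None
    ld_bin_edges: np.ndarray | None = None
    n_controls_per_case: int = 1
    seed: int = 0
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.n_controls_per_case < 1:
            raise ValueError("n_controls_per_case must be >= 1")
        for edges in (self.maf_bin_edges, self.ld_bin_edges):
            if edges is not None and np.any(np.diff(np.asarray(edges)) <= 0):
                raise ValueError("bin edges must be strictly increasing")


@dataclass
class MatchResult:
    control_indices: np.ndarray
    control_mask: AnnotationMask
    bin_table: pd.DataFrame
    n_fallback: int = 0
    pairing: pd.DataFrame | None = None


def ld_partner_count(
    panel: SnpPanel,
    ld,
    window: int = DEFAULT_WINDOW,
    r2_threshold: float = DEFAULT_R2,
) -> np.ndarray:
    """Per-SNP count of same-chromosome partners within ``window`` bases at
    r² >= ``r2_threshold``; each edge contributes to both endpoints."""
    counts = np.zeros(len(panel), dtype=int)
    for i, j, _ in ld.edges(panel, window, r2_threshold):
        counts[i] += 1
        counts[j] += 1
    return counts


def _quantile_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    return np.unique(qs)  # collapse ties so edges stay strictly increasing


def _digitize(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # bins are (e0, e1], ..., (e_{k-1}, e_k]; values outside clamp to end bins
    b = np.digitize(x, edges[1:-1], right=True)
    return b


def match_controls(
    panel: SnpPanel, case_mask: AnnotationMask, spec: MatchSpec,
    ld_counts: np.ndarray | None = None, ld=None,
) -> MatchResult:
    """Draw MAF/LD-matched non-case controls, ``n_controls_per_case`` each.

    Controls come uniformly without replacement (by default) from the case's
    joint (MAF bin, LD-partner-count bin). A bin whose non-case pool runs dry
    falls back to the nearest neighbouring bin (logged and counted); a pool
    empty everywhere raises. SNPs without MAF are excluded from both sides.
    Deterministic given ``spec.seed``.
    """
    if ld_counts is None:
        if ld is None:
            raise ValueError("provide ld_counts or an LD source")
        ld_counts = ld_partner_count(panel, ld)
    maf = panel.maf
    has_maf = ~np.isnan(maf)
    cases = np.flatnonzero(case_mask.member & has_maf)
    pool_ok = ~case_mask.member & has_maf
    if cases.size == 0:
        empty = np.zeros(len(panel), dtype=bool)
        return MatchResult(
            np.array([], dtype=int),
            AnnotationMask(f"controls_{case_mask.compendium_name}", empty),
            pd.DataFrame(columns=["maf_bin", "ld_bin", "n_cases", "n_controls", "n_fallback"]),
        )
    if not pool_ok.any():
        raise ValueError("no eligible control SNPs outside the case set")

    maf_edges = (
        np.asarray(spec.maf_bin_edges)
        if spec.maf_bin_edges is not None
        else _quantile_edges(maf[cases], 10)
    )
    ld_edges = (
        np.asarray(spec.ld_bin_edges)
        if spec.ld_bin_edges is not None
        else _quantile_edges(ld_counts[cases].astype(float), 4)
    )
    maf_bin = _digitize(maf, maf_edges)
    ld_bin = _digitize(ld_counts.astype(float), ld_edges)
    n_maf = max(len(maf_edges) - 1, 1)
    n_ld = max(len(ld_edges) - 1, 1)
    joint = maf_bin * n_ld + ld_bin

    rng = np.random.default_rng(spec.seed)
    chosen: list[int] = []
    taken = np.zeros(len(panel), dtype=bool)
    rows = []
    n_fallback_total = 0
    pairs = []
    # per-bin case counts drive the draws; bins visited in sorted order for
    # determinism
    case_bins, case_counts = np.unique(joint[cases], return_counts=True)
    for b, n_case in zip(case_bins, case_counts):
        need = int(n_case) * spec.n_controls_per_case
        mb, lb = divmod(int(b), n_ld)
        got: list[int] = []
        n_fb = 0
        # ring of bins by joint-bin distance; distance 0 is the bin itself
        for dist in range(n_maf + n_ld + 1):
            cand_bins = [
                (mb + dm) * n_ld + (lb + dl)
                for dm in range(-dist, dist + 1)
                for dl in range(-dist, dist + 1)
                if max(abs(dm), abs(dl)) == dist
                and 0 <= mb + dm < n_maf
                and 0 <= lb + dl < n_ld
            ]
            pool = np.flatnonzero(
                pool_ok & np.isin(joint, cand_bins) & (spec.with_replacement | ~taken)
            )
            if pool.size == 0:
                continue
            if spec.with_replacement:
                take = need - len(got)
                pick = rng.choice(pool, size=take, replace=True)
            else:
                take = min(need - len(got), pool.size)
                pick = rng.choice(pool, size=take, replace=False)
            if dist > 0:
                n_fb += take
            got.extend(int(x) for x in pick)
            if not spec.with_replacement:
                taken[pick] = True
            if len(got) >= need:
                break
        if len(got) < need:
            raise ValueError(
                f"control pool exhausted for bin (maf={mb}, ld={lb}): "
                f"needed {need}, found {len(got)}"
            )
        if n_fb:
            logger.warning(
                "bin (maf=%d, ld=%d): %d controls drawn from neighbouring bins",
                mb, lb, n_fb,
            )
        chosen.extend(got)
        n_fallback_total += n_fb
        rows.append(
            {"maf_bin": mb, "ld_bin": lb, "n_cases": int(n_case),
             "n_controls": len(got), "n_fallback": n_fb}
        )
        case_ids = panel.df["snp_id"].to_numpy()[cases[joint[cases] == b]]
        ctrl_ids = panel.df["snp_id"].to_numpy()[np.array(got, dtype=int)]
        for ci, cid in enumerate(case_ids):
            sl = ctrl_ids[ci * spec.n_controls_per_case:(ci + 1) * spec.n_controls_per_case]
            pairs.append({"case_snp_id": cid, "control_snp_ids": ",".join(sl)})

    idx = np.array(sorted(set(chosen)), dtype=int)
    member = np.zeros(len(panel), dtype=bool)
    member[idx] = True
    return MatchResult(
        control_indices=idx,
        control_mask=AnnotationMask(f"controls_{case_mask.compendium_name}", member),
        bin_table=pd.DataFrame(rows),
        n_fallback=n_fallback_total,
        pairing=pd.DataFrame(pairs),
    )
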