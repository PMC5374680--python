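"""Synthetic LD-structured SNP panels, peak sets, and summary statistics.

The generator emulates the statistical structure the enrichment analyses
assume, at desk scale and with full determinism under a seed:

* a SNP panel with geometric-size LD blocks of consecutive SNPs, genotype
  dosages sharing a latent haplotype per block so realized pairwise within-
  block r² is close to a target, and uniform MAF;
* H3K27Ac peak clusters that merge (gaps < 100 bp) into stretches longer
  than 2 kb, a "true enhancer" subset of which carries BRD4 (and MED12)
  sub-peaks while decoy clusters carry none;
* association p-values: uniform for null SNPs, a normal-mean shift for
  causal SNPs, with block-mates of causal SNPs inheriting attenuated signal
  proportional to r² — so LD pruning has something real to correct.

Signal placement is configurable: inside true enhancers (the enriched
alternative), uniformly over the panel (the enrichment null: significant
SNPs exist but are independent of annotation), or absent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gwas import SnpPanel
from .intervals import GenomicInterval, IntervalSet, write_bed

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_panel",
    "simulate_marks",
    "simulate_pvalues",
    "draw_causal_mask",
    "simulate_study",
    "write_study",
]

#: E[-log10 p] for p ~ Uniform(0,1): log10(e).
NULL_MEAN_NEGLOG10 = float(np.log10(np.e))


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults give 2 chromosomes x 10 Mb, 20,000 SNPs in LD blocks of mean
    size 5, 500 genotyped samples, and 40 H3K27Ac clusters (20 BRD4-positive
    true enhancers, 20 decoys) — a full pipeline run in well under a minute.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 10_000_000
    n_snps: int = 20_000
    n_samples: int = 500
    block_size_mean: float = 5.0
    max_block_size: int = 25
    within_block_r2: float = 0.8
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_true_clusters: int = 20
    n_decoy_clusters: int = 20
    peaks_per_cluster: tuple[int, int] = (4, 7)
    peak_length_range: tuple[int, int] = (500, 1000)
    peak_gap_range: tuple[int, int] = (20, 90)
    brd4_peaks_per_cluster: tuple[int, int] = (1, 3)
    brd4_length_range: tuple[int, int] = (200, 400)
    enhancer_fraction_causal: float = 0.3
    effect_neglog10_mean: float = 10.0
    causal_placement: str = "enhancer"  # enhancer | uniform | uniform_block | none
    #: exact causal count for uniform placement (None: derive from
    #: enhancer_fraction_causal times the annotation size)
    n_causal_uniform: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.within_block_r2 < 1):
            raise ValueError("within_block_r2 must lie in [0, 1)")
        if not (0 <= self.enhancer_fraction_causal <= 1):
            raise ValueError("enhancer_fraction_causal must lie in [0, 1]")
        if self.causal_placement not in ("enhancer", "uniform", "uniform_block", "none"):
            raise ValueError(
                "causal_placement must be enhancer|uniform|uniform_block|none"
            )


@dataclass
class SimResult:
    panel: SnpPanel
    genotypes: np.ndarray | None
    sparse_ld: pd.DataFrame
    block_id: np.ndarray
    marks: dict[str, IntervalSet]
    true_enhancers: IntervalSet
    decoy_clusters: IntervalSet
    causal_mask: np.ndarray
    config: SimConfig


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg_seed, spawn_key=(stream,)))


def _chrom_names(n: int) -> list[str]:
    # zero-padded so lexicographic order equals numeric order
    width = len(str(n))
    return [f"chr{str(i + 1).zfill(width) if n > 9 else i + 1}" for i in range(n)]


def simulate_panel(
    cfg: SimConfig, with_genotypes: bool = True
) -> tuple[SnpPanel, np.ndarray | None, pd.DataFrame, np.ndarray]:
    """Simulate SNP positions, MAF, LD blocks and (optionally) genotypes.

    Returns ``(panel, genotypes, sparse_ld, block_id)`` where ``genotypes``
    is a (n_snps, n_samples) int8 dosage matrix (None when skipped),
    ``sparse_ld`` a 3-column within-block r² table (realized r² from
    genotypes when available, the target otherwise), and ``block_id`` the
    panel-aligned true block labels.

    Within a block every haplotype copies a shared latent allele with
    probability ``within_block_r2 ** 0.25``, which makes the expected dosage
    correlation between two block-mates ``sqrt(within_block_r2)`` and hence
    the expected r² approximately the target.
    """
    rng = _rng(cfg.seed, 0)
    names = _chrom_names(cfg.n_chrom)
    per_chrom = np.full(cfg.n_chrom, cfg.n_snps // cfg.n_chrom)
    per_chrom[: cfg.n_snps % cfg.n_chrom] += 1

    chroms: list[str] = []
    pos_all: list[np.ndarray] = []
    for name, k in zip(names, per_chrom):
        pos = np.sort(rng.choice(cfg.chrom_length - 1, size=k, replace=False)) + 1
        pos_all.append(pos)
        chroms.extend([name] * k)
    pos_arr = np.concatenate(pos_all)
    n = cfg.n_snps

    # geometric block sizes over consecutive SNPs, restarting per chromosome
    block_id = np.empty(n, dtype=int)
    bid = 0
    offset = 0
    p_geom = 1.0 / cfg.block_size_mean
    for k in per_chrom:
        i = 0
        while i < k:
            size = min(int(rng.geometric(p_geom)), cfg.max_block_size, k - i)
            block_id[offset + i : offset + i + size] = bid
            bid += 1
            i += size
        offset += k
    n_blocks = bid

    block_maf = rng.uniform(*cfg.maf_range, size=n_blocks)
    maf = block_maf[block_id]

    genotypes: np.ndarray | None = None
    if with_genotypes:
        a = cfg.within_block_r2**0.25
        # latent allele per (haplotype copy, sample, block)
        lat = rng.random((2, cfg.n_samples, n_blocks)) < block_maf
        copy = rng.random((2, cfg.n_samples, n)) < a
        noise = rng.random((2, cfg.n_samples, n)) < maf
        hap = np.where(copy, lat[:, :, block_id], noise)
        genotypes = hap.sum(axis=0).T.astype(np.int8)  # (n_snps, n_samples)

    # within-block pairwise r² table
    rows = []
    ids = np.array([f"rs{i:07d}" for i in range(n)])
    for b in range(n_blocks):
        members = np.flatnonzero(block_id == b)
        if members.size > 1:
            if genotypes is not None:
                g = genotypes[members].astype(float)
                sd = g.std(axis=1)
                ok = sd > 0
                r2 = np.zeros((members.size, members.size))
                if ok.sum() > 1:
                    c = np.corrcoef(g[ok])
                    r2[np.ix_(ok, ok)] = c**2
            else:
                r2 = np.full((members.size, members.size), cfg.within_block_r2)
            for x in range(members.size):
                for y in range(x + 1, members.size):
                    rows.append((ids[members[x]], ids[members[y]], float(r2[x, y])))
    sparse_ld = pd.DataFrame(rows, columns=["snp_id_a", "snp_id_b", "r2"])
    if len(sparse_ld):
        sparse_ld["r2"] = sparse_ld["r2"].astype(float).clip(0.0, 1.0)

    df = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chroms,
            "pos": pos_arr,
            "pvalue": 1.0,  # placeholder until simulate_pvalues
            "maf": maf,
        }
    )
    panel = SnpPanel(df)
    # SnpPanel sorts by (chrom, pos); our construction is already in that
    # order, which keeps genotypes/block_id aligned — assert it.
    if not np.array_equal(panel.df["snp_id"].to_numpy(), ids):
        raise AssertionError("panel reordered; alignment broken")
    return panel, genotypes, sparse_ld, block_id


def _make_cluster(
    rng: np.random.Generator, cfg: SimConfig, chrom: str, anchor: int
) -> list[GenomicInterval]:
    n_peaks = rng.integers(cfg.peaks_per_cluster[0], cfg.peaks_per_cluster[1] + 1)
    peaks = []
    cursor = anchor
    for _ in range(n_peaks):
        length = int(rng.integers(*cfg.peak_length_range))
        peaks.append(GenomicInterval(chrom, cursor, cursor + length))
        cursor += length + int(rng.integers(*cfg.peak_gap_range))
    return peaks


def simulate_marks(
    cfg: SimConfig, panel: SnpPanel | None = None
) -> tuple[dict[str, IntervalSet], IntervalSet, IntervalSet]:
    """Simulate H3K27Ac clusters with BRD4/MED12 sub-peaks in true enhancers.

    Returns ``(marks, true_enhancers, decoy_clusters)``: ``marks`` holds the
    H3K27Ac, BRD4 and MED12 peak sets; the other two are the merged spans of
    the BRD4-positive and BRD4-negative clusters. Clusters are placed on an
    even grid with random offsets so they never collide or merge with each
    other.
    """
    rng = _rng(cfg.seed, 1)
    names = _chrom_names(cfg.n_chrom)
    n_clusters = cfg.n_true_clusters + cfg.n_decoy_clusters
    slots = []  # (chrom, segment_start, segment_len)
    per_chrom = np.full(cfg.n_chrom, n_clusters // cfg.n_chrom)
    per_chrom[: n_clusters % cfg.n_chrom] += 1
    for name, k in zip(names, per_chrom):
        if k == 0:
            continue
        seg = cfg.chrom_length // k
        for s in range(k):
            slots.append((name, s * seg, seg))
    is_true = np.zeros(len(slots), dtype=bool)
    is_true[rng.choice(len(slots), size=cfg.n_true_clusters, replace=False)] = True

    h3k27ac: list[GenomicInterval] = []
    brd4: list[GenomicInterval] = []
    med12: list[GenomicInterval] = []
    true_spans: list[GenomicInterval] = []
    decoy_spans: list[GenomicInterval] = []
    # worst-case cluster footprint, to keep clusters inside their slot
    max_span = cfg.peaks_per_cluster[1] * (
        cfg.peak_length_range[1] + cfg.peak_gap_range[1]
    )
    for (chrom, seg_start, seg_len), truth in zip(slots, is_true):
        margin = max(seg_len - max_span - 1, 1)
        anchor = seg_start + int(rng.integers(0, margin))
        peaks = _make_cluster(rng, cfg, chrom, anchor)
        h3k27ac.extend(peaks)
        span = GenomicInterval(chrom, peaks[0].start, peaks[-1].end)
        if truth:
            true_spans.append(span)
            for sub, store in ((cfg.brd4_peaks_per_cluster, brd4), ((1, 2), med12)):
                k = int(rng.integers(sub[0], sub[1] + 1))
                for _ in range(k):
                    length = int(rng.integers(*cfg.brd4_length_range))
                    start = int(rng.integers(span.start, max(span.end - length, span.start + 1)))
                    store.append(GenomicInterval(chrom, start, start + length))
        else:
            decoy_spans.append(span)

    marks = {
        "H3K27Ac": IntervalSet(h3k27ac, name="H3K27Ac"),
        "BRD4": IntervalSet(brd4, name="BRD4"),
        "MED12": IntervalSet(med12, name="MED12"),
    }
    return (
        marks,
        IntervalSet(true_spans, name="true_enhancers"),
        IntervalSet(decoy_spans, name="decoy_clusters"),
    )


def effect_mean_to_mu(effect_neglog10_mean: float) -> float:
    """Normal mean giving a median -log10 p of (null mean + effect)."""
    target = NULL_MEAN_NEGLOG10 + effect_neglog10_mean
    return float(norm.isf(0.5 * 10.0 ** (-target)))


def draw_causal_mask(
    cfg: SimConfig,
    panel: SnpPanel,
    enhancer_member: np.ndarray,
    block_id: np.ndarray | None = None,
) -> np.ndarray:
    """Choose causal SNPs per the configured placement.

    ``enhancer``: each true-enhancer SNP is causal independently with
    probability ``enhancer_fraction_causal``. ``uniform``: causal SNPs drawn
    uniformly from the whole panel regardless of annotation — a null of the
    *enrichment* test, under which genome-wide-significant SNPs exist but
    carry no information about membership. ``uniform_block``: causal *blocks*
    drawn uniformly, one causal SNP each — the block-level enrichment null,
    under which the per-block probability of carrying signal is homogeneous
    (uniform SNP-level placement makes large blocks likelier to be causal,
    which under-disperses the conditional 2x2 table and turns the exact test
    conservative). ``none``: no causal SNPs (fully uniform p-values).

    For the uniform modes, ``n_causal_uniform`` fixes the count (of SNPs or
    blocks respectively); otherwise it derives from
    ``enhancer_fraction_causal`` times the annotation size.
    """
    rng = _rng(cfg.seed, 2)
    n = len(panel)
    causal = np.zeros(n, dtype=bool)
    if cfg.causal_placement == "none":
        return causal
    members = np.flatnonzero(enhancer_member)
    n_uniform = (
        cfg.n_causal_uniform
        if cfg.n_causal_uniform is not None
        else int(round(cfg.enhancer_fraction_causal * members.size))
    )
    if cfg.causal_placement == "enhancer":
        if cfg.enhancer_fraction_causal > 0:
            causal[members] = rng.random(members.size) < cfg.enhancer_fraction_causal
    elif cfg.causal_placement == "uniform":
        n_causal = min(n, n_uniform)
        if n_causal:
            causal[rng.choice(n, size=n_causal, replace=False)] = True
    else:  # uniform_block
        if block_id is None:
            raise ValueError("uniform_block placement requires block_id")
        n_blocks = int(block_id.max()) + 1
        n_causal = min(n_blocks, n_uniform)
        if n_causal:
            for b in rng.choice(n_blocks, size=n_causal, replace=False):
                members_b = np.flatnonzero(block_id == b)
                causal[rng.choice(members_b)] = True
    return causal


def simulate_pvalues(
    cfg: SimConfig,
    panel: SnpPanel,
    causal_mask: np.ndarray,
    block_id: np.ndarray,
) -> np.ndarray:
    """Draw association p-values into the panel (in place) and return them.

    Null SNPs get p ~ Uniform(0,1). Causal SNPs draw z ~ Normal(mu, 1) with
    mu set from ``effect_neglog10_mean`` and take the two-sided normal tail.
    Non-causal block-mates of a causal SNP inherit z' = sqrt(r2) z +
    sqrt(1 - r2) eps with the block's target r², so tag SNPs show attenuated
    signal and pruning is meaningful.
    """
    rng = _rng(cfg.seed, 3)
    n = len(panel)
    causal_mask = np.asarray(causal_mask, dtype=bool)
    p = rng.uniform(0.0, 1.0, size=n)
    if causal_mask.any():
        mu = effect_mean_to_mu(cfg.effect_neglog10_mean)
        z_causal = rng.normal(mu, 1.0, size=int(causal_mask.sum()))
        z = np.zeros(n)
        z[causal_mask] = z_causal
        # block-mates inherit from one causal SNP of their block
        causal_blocks = {}
        for i in np.flatnonzero(causal_mask):
            causal_blocks.setdefault(block_id[i], i)
        r2 = cfg.within_block_r2
        for i in range(n):
            if causal_mask[i]:
                continue
            src = causal_blocks.get(block_id[i])
            if src is not None:
                z[i] = np.sqrt(r2) * z[src] + np.sqrt(1.0 - r2) * rng.normal()
        affected = z != 0
        p[affected] = 2.0 * norm.sf(np.abs(z[affected]))
    p = np.clip(p, 1e-300, 1.0)
    panel.df["pvalue"] = p
    return p


def simulate_study(cfg: SimConfig, with_genotypes: bool = True) -> SimResult:
    """Generate a full study: panel, genotypes, LD, marks, truth, p-values."""
    from .gwas import annotate  # local import avoids cycle at module load

    panel, genotypes, sparse_ld, block_id = simulate_panel(cfg, with_genotypes)
    marks, true_enh, decoys = simulate_marks(cfg, panel)
    member = annotate(panel, true_enh).member
    causal = draw_causal_mask(cfg, panel, member, block_id)
    simulate_pvalues(cfg, panel, causal, block_id)
    return SimResult(
        panel=panel,
        genotypes=genotypes,
        sparse_ld=sparse_ld,
        block_id=block_id,
        marks=marks,
        true_enhancers=true_enh,
        decoy_clusters=decoys,
        causal_mask=causal,
        config=cfg,
    )


def write_study(result: SimResult, outdir: str | Path) -> Path:
    """Write a study to disk: marks/*.bed, panel.tsv, LD table, truth.json."""
    outdir = Path(outdir)
    (outdir / "marks").mkdir(parents=True, exist_ok=True)
    for name, iset in result.marks.items():
        write_bed(iset, outdir / "marks" / f"{name}.bed")
    write_bed(result.true_enhancers, outdir / "marks" / "true_enhancers.bed")
    result.panel.df.to_csv(outdir / "panel.tsv", sep="\t", index=False)
    result.sparse_ld.to_csv(outdir / "ld_pairs.tsv", sep="\t", index=False)
    if result.genotypes is not None:
        g = pd.DataFrame(
            result.genotypes,
            columns=[f"s{j}" for j in range(result.genotypes.shape[1])],
        )
        g.insert(0, "snp_id", result.panel.df["snp_id"].to_numpy())
        g.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    truth = {
        "causal_snp_ids": result.panel.df["snp_id"][result.causal_mask].tolist(),
        "true_enhancers": [
            [iv.chrom, iv.start, iv.end] for iv in result.true_enhancers
        ],
        "config": asdict(result.config),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=int)  # numpy scalars -> int
    return outdir
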