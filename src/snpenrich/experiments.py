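"""Designed simulation experiments: null calibration, power ordering, recovery.

These functions define the package's standard in-silico experiments — the
study conditions under which the enrichment machinery is validated:

* **Null calibration**: panels where genome-wide-significant SNPs exist but
  are placed at the LD-block level independently of annotation membership,
  so the over-representation test's type-I error can be measured. Placement
  is block-level because block-level exchangeability is what makes the
  conditional 2x2 table exactly hypergeometric after pruning; and the
  calibration scale is chosen so expected significant-member counts are
  large (E[k] ~ 70) — at small counts an exact discrete test is conservative
  by construction and its attainable level, not its calibration, is what a
  small-count experiment would measure.
* **Ordering (power)**: studies with signal injected only into BRD4-positive
  clusters, where the BRD4-intersected compendium should test as more
  enriched than stitched H3K27Ac alone.
* **Recipe recovery**: peak sets with known true/decoy clusters, where the
  stitched-H3K27Ac + BRD4 recipe should return exactly the true clusters.

Each experiment derives per-replicate seeds from one base seed, so a single
integer reproduces the whole experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .enrichment import fisher_enrichment
from .gwas import AnnotationMask, SnpPanel, annotate
from .intervals import build_compendium
from .ld import SparseLd
from .matching import MatchSpec, ld_partner_count, match_controls
from .pruning import build_ld_blocks, random_prune
from .synthetic import SimConfig, simulate_marks, simulate_study

__all__ = [
    "derive_seed",
    "null_calibration_config",
    "null_calibration",
    "ordering_fraction",
    "recovery_fraction",
    "CalibrationResult",
]


def derive_seed(base: int, index: int) -> int:
    """Per-replicate seed, reproducible from (base, index), below 2^31."""
    return int(
        np.random.SeedSequence(base, spawn_key=(index,)).generate_state(1)[0]
        % (2**31)
    )


def null_calibration_config(seed: int) -> SimConfig:
    """Study conditions for one null-calibration panel.

    10,000 SNPs on 2 x 10 Mb, LD blocks of mean size 3, 120 H3K27Ac clusters
    (~10% of SNPs annotated), 800 causal blocks placed uniformly regardless
    of annotation. The effect is set large enough (z-mean ~ 10.3) that a
    causal block's pruned representative crosses the genome-wide threshold
    with probability ~ 1 whether it is the causal SNP itself or an
    r2-attenuated block-mate: per-block significance probability must be
    homogeneous for block-level exchangeability — and hence the exact
    conditional hypergeometric null — to hold. At moderate effects the
    representative-is-a-tag-SNP case is measurably less likely to cross,
    which tilts the significant set and makes the test conservative.
    """
    return SimConfig(
        seed=seed,
        n_chrom=2,
        chrom_length=10_000_000,
        n_snps=10_000,
        block_size_mean=3.0,
        within_block_r2=0.8,
        n_true_clusters=60,
        n_decoy_clusters=60,
        peaks_per_cluster=(8, 12),
        peak_length_range=(1000, 2000),
        causal_placement="uniform_block",
        n_causal_uniform=800,
        effect_neglog10_mean=24.0,
    )


@dataclass
class CalibrationResult:
    n_panels: int
    rejections_panel_background: int
    rejections_control_background: int

    @property
    def rate_panel(self) -> float:
        return self.rejections_panel_background / self.n_panels

    @property
    def rate_controls(self) -> float:
        return self.rejections_control_background / self.n_panels

    def within_band(self, alpha: float = 0.05, n_se: float = 3.0) -> tuple[bool, bool]:
        half = n_se * np.sqrt(alpha * (1 - alpha) / self.n_panels)
        lo, hi = alpha - half, alpha + half
        return (lo <= self.rate_panel <= hi, lo <= self.rate_controls <= hi)


def null_calibration(
    n_panels: int = 1000,
    base_seed: int = 0,
    alpha: float = 0.05,
    n_controls_per_case: int = 4,
) -> CalibrationResult:
    """Empirical type-I error of the over-representation test on pruned null
    panels, for the whole-panel and matched-control backgrounds.

    Each replicate simulates a fresh panel under the enrichment null, builds
    the stitched-H3K27Ac annotation, LD-prunes (one random representative per
    block), runs the one-sided hypergeometric test at the genome-wide
    threshold against both backgrounds, and counts rejections at ``alpha``.
    """
    rej_panel = 0
    rej_ctrl = 0
    for i in range(n_panels):
        cfg = null_calibration_config(derive_seed(base_seed, i))
        res = simulate_study(cfg, with_genotypes=False)
        comp = build_compendium("HNISZ_generic", res.marks)
        mask = annotate(res.panel, comp)
        ld = SparseLd(res.sparse_ld)
        assignment = build_ld_blocks(res.panel, ld)
        keep = random_prune(assignment, derive_seed(base_seed, 10_000_000 + i))
        sub = SnpPanel(res.panel.df.iloc[keep].reset_index(drop=True))
        sub_mask = AnnotationMask(mask.compendium_name, mask.member[keep])
        if fisher_enrichment(sub, sub_mask).p_hyper < alpha:
            rej_panel += 1
        ld_counts = ld_partner_count(res.panel, ld)[keep]
        controls = match_controls(
            sub,
            sub_mask,
            MatchSpec(
                n_controls_per_case=n_controls_per_case,
                seed=derive_seed(base_seed, 20_000_000 + i),
            ),
            ld_counts=ld_counts,
        ).control_mask
        if fisher_enrichment(sub, sub_mask, background=controls).p_hyper < alpha:
            rej_ctrl += 1
    return CalibrationResult(n_panels, rej_panel, rej_ctrl)


def ordering_fraction(
    n_seeds: int = 100, base_seed: int = 0, cfg: SimConfig | None = None
) -> float:
    """Fraction of studies in which the BRD4-intersected compendium attains a
    strictly smaller over-representation p than stitched H3K27Ac alone, with
    signal injected only into BRD4-positive clusters."""
    wins = 0
    template = cfg if cfg is not None else SimConfig()
    for i in range(n_seeds):
        res = simulate_study(
            replace(template, seed=derive_seed(base_seed, i)), with_genotypes=False
        )
        comp_h3 = build_compendium("HNISZ_generic", res.marks, name="H3K27Ac")
        comp_brd4 = build_compendium(
            "HNISZ_generic", res.marks, binding_marks=["BRD4"], name="H3K27Ac_BRD4"
        )
        p_h3 = fisher_enrichment(res.panel, annotate(res.panel, comp_h3)).p_hyper
        p_brd4 = fisher_enrichment(res.panel, annotate(res.panel, comp_brd4)).p_hyper
        wins += p_brd4 < p_h3
    return wins / n_seeds


def recovery_fraction(n_seeds: int = 50, base_seed: int = 0) -> float:
    """Fraction of seeds in which the stitched-H3K27Ac + BRD4 recipe returns
    exactly the 10 true (BRD4-bearing) clusters out of 10 true + 10 decoys."""
    hits = 0
    for i in range(n_seeds):
        cfg = SimConfig(
            seed=derive_seed(base_seed, i), n_true_clusters=10, n_decoy_clusters=10
        )
        marks, true_enh, _ = simulate_marks(cfg)
        comp = build_compendium("HNISZ_generic", marks, binding_marks=["BRD4"])
        hits += comp.intervals == true_enh
    return hits / n_seeds
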