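"""GWAS summary-statistic panels, annotation masks, and count tables.

Summary-statistic positions are 1-based (the GWAS convention); annotation
intervals are 0-based half-open (BED). The conversion happens in exactly one
place: the membership predicate of :func:`annotate`. A SNP at 1-based
position ``p`` lies in ``[start, end)`` iff ``start <= p - 1 < end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import EnhancerCompendium, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "AnnotationMask",
    "SnpPanel",
    "read_summary_stats",
    "write_panel",
    "annotate",
    "count_table",
    "canonical_chrom",
]

#: p-values of exactly 0 in input files are floored to this before -log10.
PVALUE_FLOOR = 1e-300

_STANDARD_CONTIGS = {str(i) for i in range(1, 23)} | {"X", "Y"}


def canonical_chrom(chrom: str) -> str:
    """Map "chr1"/"1" to the single internal dialect ("chr1").

    Mitochondrial and haplotype/patch contigs pass through verbatim, except
    that bare "MT"/"M" gains the prefix for consistency with "chrM" inputs.
    """
    c = chrom.strip()
    body = c[3:] if c.lower().startswith("chr") else c
    if body in _STANDARD_CONTIGS or body in {"M", "MT"}:
        return "chr" + ("M" if body == "MT" else body)
    return c


@dataclass(frozen=True)
class SnpRecord:
    """One GWAS marker."""

    snp_id: str
    chrom: str
    pos: int  # 1-based
    pvalue: float
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.snp_id}: pvalue {self.pvalue} not in (0, 1]")
        if self.maf is not None and not (0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf {self.maf} not in (0, 0.5]")


@dataclass
class AnnotationMask:
    """Per-SNP membership flags for one compendium, aligned to a panel."""

    compendium_name: str
    member: np.ndarray  # bool, len == panel size

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)

    @property
    def n_members(self) -> int:
        return int(self.member.sum())


class SnpPanel:
    """An ordered SNP panel held as a DataFrame, plus annotation masks.

    Columns: ``snp_id, chrom, pos, pvalue, maf`` (maf may hold NaN). Rows are
    sorted by (chrom, pos); snp_ids are unique.
    """

    def __init__(self, df: pd.DataFrame, masks: Sequence[AnnotationMask] = ()):
        required = {"snp_id", "chrom", "pos", "pvalue"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel missing columns {sorted(missing)}")
        df = df.copy()
        if "maf" not in df.columns:
            df["maf"] = np.nan
        df["chrom"] = df["chrom"].astype(str).map(canonical_chrom)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        dup = df["snp_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate snp_id(s): {df.loc[dup, 'snp_id'].unique()[:5].tolist()}"
            )
        bad_p = ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
        if bad_p.any():
            raise ValueError("panel contains p-values outside (0, 1]")
        self.df = df
        self.masks: dict[str, AnnotationMask] = {}
        for m in masks:
            self.add_mask(m)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pvalues(self) -> np.ndarray:
        return self.df["pvalue"].to_numpy()

    @property
    def maf(self) -> np.ndarray:
        return self.df["maf"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    def add_mask(self, mask: AnnotationMask) -> None:
        if len(mask.member) != len(self):
            raise ValueError(
                f"mask {mask.compendium_name!r} has {len(mask.member)} flags "
                f"for a panel of {len(self)}"
            )
        self.masks[mask.compendium_name] = mask

    def records(self) -> list[SnpRecord]:
        return [
            SnpRecord(
                r.snp_id,
                r.chrom,
                int(r.pos),
                float(r.pvalue),
                None if pd.isna(r.maf) else float(r.maf),
            )
            for r in self.df.itertuples(index=False)
        ]


DEFAULT_COLUMN_MAP = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "pvalue": "pvalue",
    "maf": "maf",
}


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
    pvalue_floor: float = PVALUE_FLOOR,
) -> SnpPanel:
    """Read delimited summary statistics into a validated :class:`SnpPanel`.

    ``column_map`` maps the canonical names (snp_id, chrom, pos, pvalue, maf)
    to the file's column headers; maf is optional. Rows with p-values outside
    (0, 1] are dropped with a logged count; exact zeros are floored to
    ``pvalue_floor`` with a warning instead of dropped.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep)
    for canon in ("snp_id", "chrom", "pos", "pvalue"):
        if cmap[canon] not in raw.columns:
            raise KeyError(
                f"{path}: required column {cmap[canon]!r} (for {canon}) not found"
            )
    df = pd.DataFrame(
        {
            "snp_id": raw[cmap["snp_id"]].astype(str),
            "chrom": raw[cmap["chrom"]].astype(str),
            "pos": raw[cmap["pos"]].astype(np.int64),
            "pvalue": raw[cmap["pvalue"]].astype(float),
        }
    )
    df["maf"] = (
        raw[cmap["maf"]].astype(float) if cmap["maf"] in raw.columns else np.nan
    )
    zero = df["pvalue"] == 0
    if zero.any():
        logger.warning(
            "%s: %d p-values of exactly 0 floored to %g", path, zero.sum(), pvalue_floor
        )
        df.loc[zero, "pvalue"] = pvalue_floor
    bad = ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
    if bad.any():
        logger.warning("%s: rejected %d rows with p-values outside (0, 1]", path, bad.sum())
        df = df[~bad]
    return SnpPanel(df.reset_index(drop=True))


def write_panel(panel: SnpPanel, path: str | Path) -> None:
    """Write the panel as TSV with one boolean column per annotation mask."""
    out = panel.df.copy()
    for name, mask in panel.masks.items():
        out[f"in_{name}"] = mask.member
    out.to_csv(path, sep="\t", index=False)


def annotate(panel: SnpPanel, compendium: EnhancerCompendium | IntervalSet) -> AnnotationMask:
    """Flag each SNP that falls inside the compendium's intervals.

    Uses a searchsorted sweep per chromosome over the normalized intervals;
    membership of a 1-based position ``p`` means some interval satisfies
    ``start <= p - 1 < end``.
    """
    if isinstance(compendium, EnhancerCompendium):
        name, iset = compendium.name, compendium.intervals
    else:
        name, iset = compendium.name, compendium
    iset = iset.normalize()
    member = np.zeros(len(panel), dtype=bool)
    by_chrom = {canonical_chrom(c): ivs for c, ivs in iset.by_chrom().items()}
    chroms = panel.chroms
    pos0 = panel.positions - 1  # to 0-based
    for chrom, ivs in by_chrom.items():
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        # normalized + sorted: interval index whose start is <= pos
        idx = np.searchsorted(starts, pos0[sel], side="right") - 1
        ok = idx >= 0
        hit = np.zeros(sel.sum(), dtype=bool)
        hit[ok] = pos0[sel][ok] < ends[idx[ok]]
        member[sel] = hit
    return AnnotationMask(compendium_name=name, member=member)


def count_table(
    panel: SnpPanel,
    masks: Sequence[AnnotationMask] | None = None,
    cross_mask: AnnotationMask | None = None,
) -> pd.DataFrame:
    """Per-annotation SNP counts, optionally crossed with a second mask
    (e.g. AR/ER-bound subsets of each enhancer compendium)."""
    if masks is None:
        masks = list(panel.masks.values())
    rows = []
    for m in masks:
        row = {
            "annotation": m.compendium_name,
            "n_snps": m.n_members,
        }
        if cross_mask is not None:
            row[f"n_snps_and_{cross_mask.compendium_name}"] = int(
                (m.member & cross_mask.member).sum()
            )
        rows.append(row)
    return pd.DataFrame(rows)
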