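"""Genomic-interval algebra and enhancer-compendium recipes.

All coordinates are 0-based half-open (BED convention) internally; conversion
from 1-based SNP positions happens only inside the overlap predicate of
:mod:`snpenrich.gwas`.

Super-enhancer compendia are built from called peak intervals by composing
three primitives: merging peaks separated by less than a gap threshold,
keeping only stretches above a length threshold, and filtering stretches for
overlap with a binding mark (BRD4, MED12, AR/ER...). The recipes encode the
cell-line-specific definitions used for LNCaP, VCaP, the prostate-cancer
consensus, and the generic Hnisz-style stitched-H3K27Ac definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "EnhancerCompendium",
    "read_bed",
    "write_bed",
    "merge_within_gap",
    "filter_by_length",
    "intersect_filter",
    "intersect_clip",
    "build_compendium",
    "RECIPES",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered, named collection of :class:`GenomicInterval`.

    Intervals are always kept sorted by ``(chrom, start, end)``. A set is
    *normalized* when no two intervals on the same chromosome overlap;
    :meth:`normalize` merges any that do.
    """

    def __init__(
        self, intervals: Iterable[GenomicInterval] = (), name: str = ""
    ) -> None:
        self.name = name
        self.intervals: list[GenomicInterval] = sorted(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(name={self.name!r}, n={len(self)})"

    def total_bases(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def chromosomes(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def is_normalized(self) -> bool:
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                return False
        return True

    def normalize(self, name: str | None = None) -> "IntervalSet":
        """Merge overlapping (not merely abutting) same-chromosome intervals."""
        return merge_within_gap(self, max_gap=0, name=name or self.name)


@dataclass
class EnhancerCompendium:
    """A named enhancer map with full provenance of the recipe that built it."""

    name: str
    intervals: IntervalSet
    recipe: dict = field(default_factory=dict)
    source_marks: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path: str | Path, name: str | None = None) -> IntervalSet:
    """Read a BED3+ file into a sorted :class:`IntervalSet`.

    ``track``/``browser``/``#`` lines and blank lines are skipped. Coordinates
    are taken as 0-based half-open per the BED standard.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated toy files
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from exc
            if end <= start or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            intervals.append(GenomicInterval(chrom, start, end))
    return IntervalSet(intervals, name=name if name is not None else path.stem)


def write_bed(s: IntervalSet, path: str | Path) -> None:
    """Write a sorted BED file; the set name, if any, goes in column 4."""
    with open(path, "w") as fh:
        for iv in sorted(s.intervals):
            if s.name:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Interval algebra


def merge_within_gap(
    s: IntervalSet, max_gap: int, name: str | None = None
) -> IntervalSet:
    """Unite same-chromosome intervals whose gap is *strictly* less than
    ``max_gap`` ("peaks closer than 100 bp were merged"), transitively.

    Overlapping or abutting intervals always merge (gap <= 0 < max_gap for
    any max_gap >= 0 is treated as "closer"). ``max_gap=0`` therefore merges
    exactly the overlapping intervals, i.e. normalizes the set.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: list[GenomicInterval] = []
    for iv in sorted(s.intervals):
        if merged and iv.chrom == merged[-1].chrom:
            prev = merged[-1]
            gap = iv.start - prev.end
            # gap < max_gap merges (strict); overlap/abutting always merges
            if gap < max_gap or gap <= 0:
                merged[-1] = GenomicInterval(
                    prev.chrom, prev.start, max(prev.end, iv.end)
                )
                continue
        merged.append(iv)
    return IntervalSet(merged, name=name if name is not None else s.name)


def filter_by_length(
    s: IntervalSet,
    min_len: int,
    max_len: int | None = None,
    name: str | None = None,
) -> IntervalSet:
    """Keep intervals strictly longer than ``min_len`` and, if bounded, no
    longer than ``max_len`` ("stretches longer than 2000 bp"; "ranging from
    3000 bp to 200 kb")."""
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    if max_len is not None and max_len <= min_len:
        raise ValueError("max_len must exceed min_len")
    kept = [
        iv
        for iv in s.intervals
        if iv.length > min_len and (max_len is None or iv.length <= max_len)
    ]
    return IntervalSet(kept, name=name if name is not None else s.name)


def _overlap_bases(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def intersect_filter(
    stretches: IntervalSet,
    marks: IntervalSet,
    min_overlap: int = 1,
    name: str | None = None,
) -> IntervalSet:
    """Keep each stretch that shares >= ``min_overlap`` bases with the mark
    set, retaining the stretch's full coordinates.

    This is overlap-*filtering*, not base-wise clipping: the unit of a
    super-enhancer analysis is the stretch, and a stretch containing a BRD4
    site counts whole. Shared bases are counted against the normalized mark
    set (equivalently, per base), so two nearby marks can jointly satisfy the
    threshold. See :func:`intersect_clip` for literal intersection.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    marks_by_chrom = {
        c: (np.array([iv.start for iv in ivs]), np.array([iv.end for iv in ivs]))
        for c, ivs in marks.normalize().by_chrom().items()
    }
    kept: list[GenomicInterval] = []
    for iv in stretches.intervals:
        if iv.chrom not in marks_by_chrom:
            continue
        starts, ends = marks_by_chrom[iv.chrom]
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        if int(ov[ov > 0].sum()) >= min_overlap:
            kept.append(iv)
    return IntervalSet(kept, name=name if name is not None else stretches.name)


def intersect_clip(
    stretches: IntervalSet, marks: IntervalSet, name: str | None = None
) -> IntervalSet:
    """Literal base-wise intersection (the ``--clip`` sensitivity mode)."""
    marks_norm = marks.normalize()
    out: list[GenomicInterval] = []
    for iv in stretches.intervals:
        for m in marks_norm.intervals:
            if iv.overlaps(m):
                out.append(
                    GenomicInterval(
                        iv.chrom, max(iv.start, m.start), min(iv.end, m.end)
                    )
                )
    return IntervalSet(out, name=name if name is not None else stretches.name).normalize()


# ---------------------------------------------------------------------------
# Recipes

#: Default recipe parameters, in bases.
DEFAULT_PARAMS = {
    "merge_gap": 100,       # peaks closer than this merge (strict <)
    "min_len_extended": 3000,   # "ranging from 3000 bp to 200 kb"
    "max_len_extended": 200_000,
    "min_len_stretch": 2000,    # "stretches longer than 2000 bp"
    "min_overlap": 1,
}

RECIPES = (
    "LNCaP_H3K27Ac",
    "LNCaP_H3K27Ac_MED12",
    "VCaP_H3K27Ac",
    "VCaP_H3K27Ac_BRD4",
    "VCaP_BRD4",
    "PC_consensus",
    "HNISZ_generic",
)


def _require(marks: Mapping[str, IntervalSet], *names: str) -> None:
    for n in names:
        if n not in marks:
            raise KeyError(f"recipe requires mark {n!r}; available: {sorted(marks)}")


def _extended_stretches(
    peaks: IntervalSet, p: Mapping[str, int], bounded: bool
) -> IntervalSet:
    merged = merge_within_gap(peaks, p["merge_gap"])
    if bounded:
        return filter_by_length(merged, p["min_len_extended"], p["max_len_extended"])
    return filter_by_length(merged, p["min_len_stretch"], None)


def build_compendium(
    recipe_id: str,
    marks: Mapping[str, IntervalSet],
    params: Mapping[str, int] | None = None,
    binding_marks: Sequence[str] = (),
    name: str | None = None,
) -> EnhancerCompendium:
    """Build one enhancer compendium by a named recipe.

    Recipes (marks are keys into ``marks``):

    - ``LNCaP_H3K27Ac``: stitched LNCaP H3K27Ac stretches of 3 kb-200 kb.
    - ``LNCaP_H3K27Ac_MED12``: the above, filtered for MED12 binding.
    - ``VCaP_H3K27Ac``: stitched VCaP H3K27Ac stretches of 3 kb-200 kb.
    - ``VCaP_H3K27Ac_BRD4``: VCaP H3K27Ac stretches > 2 kb with a BRD4 site.
    - ``VCaP_BRD4``: the raw BRD4 binding sites.
    - ``PC_consensus``: LNCaP H3K27Ac+MED12 intervals that also overlap both
      a VCaP H3K27Ac stretch and a VCaP BRD4 site.
    - ``HNISZ_generic``: merge gaps < ``merge_gap``, keep length >
      ``min_len_stretch``, then optionally filter for each mark named in
      ``binding_marks`` (used for MCF7/H2171/Schwann-style compendia).
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    used: list[str] = []

    if recipe_id == "LNCaP_H3K27Ac":
        _require(marks, "LNCaP_H3K27Ac")
        out = _extended_stretches(marks["LNCaP_H3K27Ac"], p, bounded=True)
        used = ["LNCaP_H3K27Ac"]
    elif recipe_id == "LNCaP_H3K27Ac_MED12":
        _require(marks, "LNCaP_H3K27Ac", "LNCaP_MED12")
        stretches = _extended_stretches(marks["LNCaP_H3K27Ac"], p, bounded=True)
        out = intersect_filter(stretches, marks["LNCaP_MED12"], p["min_overlap"])
        used = ["LNCaP_H3K27Ac", "LNCaP_MED12"]
    elif recipe_id == "VCaP_H3K27Ac":
        _require(marks, "VCaP_H3K27Ac")
        out = _extended_stretches(marks["VCaP_H3K27Ac"], p, bounded=True)
        used = ["VCaP_H3K27Ac"]
    elif recipe_id == "VCaP_H3K27Ac_BRD4":
        _require(marks, "VCaP_H3K27Ac", "VCaP_BRD4")
        stretches = _extended_stretches(marks["VCaP_H3K27Ac"], p, bounded=False)
        out = intersect_filter(stretches, marks["VCaP_BRD4"], p["min_overlap"])
        used = ["VCaP_H3K27Ac", "VCaP_BRD4"]
    elif recipe_id == "VCaP_BRD4":
        _require(marks, "VCaP_BRD4")
        out = IntervalSet(marks["VCaP_BRD4"].intervals)
        used = ["VCaP_BRD4"]
    elif recipe_id == "PC_consensus":
        _require(marks, "LNCaP_H3K27Ac", "LNCaP_MED12", "VCaP_H3K27Ac", "VCaP_BRD4")
        lncap = build_compendium("LNCaP_H3K27Ac_MED12", marks, p).intervals
        vcap_stretch = _extended_stretches(marks["VCaP_H3K27Ac"], p, bounded=False)
        out = intersect_filter(lncap, vcap_stretch, p["min_overlap"])
        out = intersect_filter(out, marks["VCaP_BRD4"], p["min_overlap"])
        used = ["LNCaP_H3K27Ac", "LNCaP_MED12", "VCaP_H3K27Ac", "VCaP_BRD4"]
    elif recipe_id == "HNISZ_generic":
        _require(marks, "H3K27Ac")
        out = _extended_stretches(marks["H3K27Ac"], p, bounded=False)
        used = ["H3K27Ac"]
        for bm in binding_marks:
            _require(marks, bm)
            out = intersect_filter(out, marks[bm], p["min_overlap"])
            used.append(bm)
    else:
        raise ValueError(f"unknown recipe {recipe_id!r}; choose from {RECIPES}")

    out = IntervalSet(out.intervals, name=name or recipe_id)
    return EnhancerCompendium(
        name=name or recipe_id,
        intervals=out,
        recipe={
            "recipe_id": recipe_id,
            "params": {k: p[k] for k in DEFAULT_PARAMS},
            "binding_marks": list(binding_marks),
        },
        source_marks=used,
    )
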