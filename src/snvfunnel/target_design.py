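"""Capture target-region design.

From the selected gene models, the design takes every coding-exon
segment, every UTR exon segment and a fixed-length promoter window
upstream of the transcript start (introns are excluded), expands short
regions symmetrically to a minimum capture-friendly length, and fuses
regions that come to overlap.  The summary counts regions, total target
bases and the protein-coding subset of those bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_models import (
    DEFAULT_PROMOTER_LEN,
    GeneModel,
    GenomicInterval,
    RegionClass,
)

logger = logging.getLogger("snvfunnel")

DEFAULT_MIN_REGION_LEN = 250


@dataclass(frozen=True)
class TargetDesign:
    """A finished design: sorted disjoint regions plus summary counts."""

    regions: tuple[GenomicInterval, ...]
    n_regions: int
    total_bases: int
    coding_bases: int

    def __post_init__(self) -> None:
        for a, b in zip(self.regions, self.regions[1:]):
            if (a.chrom, a.start) > (b.chrom, b.start):
                raise ValueError("design regions not sorted")
            if a.overlaps(b):
                raise ValueError("design regions overlap")
        if self.total_bases != sum(len(r) for r in self.regions):
            raise ValueError("total_bases inconsistent with regions")
        if not 0 <= self.coding_bases <= self.total_bases:
            raise ValueError("coding_bases out of range")

    def chrom_masks(self, chrom_lengths: Mapping[str, int]
                    ) -> dict[str, np.ndarray]:
        """Boolean target membership per chromosome."""
        masks = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
        for r in self.regions:
            masks[r.chrom][r.start:r.end] = True
        return masks


def extract_raw_regions(genes: Sequence[GeneModel],
                        promoter_len: int = DEFAULT_PROMOTER_LEN,
                        chrom_lengths: Mapping[str, int] | None = None,
                        ) -> list[GenomicInterval]:
    """Per-gene raw target intervals: promoter + every exonic segment.

    Exons are split at the CDS bounds so each interval is purely UTR or
    purely coding; region strand is dropped (capture is strand-agnostic).
    Promoter windows falling entirely off-chromosome are dropped with a
    warning.
    """
    out: list[GenomicInterval] = []
    for g in genes:
        clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
        prom = g.promoter_interval(promoter_len, clen)
        if prom is None:
            logger.warning("gene %s: promoter window entirely off-chromosome; "
                           "dropped", g.gene_id)
        else:
            out.append(GenomicInterval(g.chrom, prom[0], prom[1]))
        for s, e in g.exons:
            # split the exon at the CDS bounds
            cuts = sorted({s, e, min(max(g.cds_start, s), e),
                           min(max(g.cds_end, s), e)})
            for lo, hi in zip(cuts, cuts[1:]):
                if lo < hi:
                    out.append(GenomicInterval(g.chrom, lo, hi))
    return out


def pad_regions(regions: Sequence[GenomicInterval],
                min_len: int = DEFAULT_MIN_REGION_LEN,
                chrom_lengths: Mapping[str, int] | None = None,
                ) -> list[GenomicInterval]:
    """Expand every region below ``min_len`` to at least ``min_len`` bases.

    The deficit is split symmetrically, the odd base going to the 3' side
    in chromosome coordinates; clamping at a chromosome bound pushes the
    clamped share to the other side, so the target length is reached
    unless the chromosome itself is shorter.
    """
    out = []
    for r in regions:
        clen = chrom_lengths.get(r.chrom) if chrom_lengths else None
        deficit = min_len - len(r)
        if deficit <= 0:
            out.append(r)
            continue
        start = r.start - deficit // 2
        end = r.end + (deficit - deficit // 2)
        if start < 0:
            end += -start
            start = 0
        if clen is not None and end > clen:
            start = max(0, start - (end - clen))
            end = clen
        out.append(GenomicInterval(r.chrom, start, end, r.strand))
    return out


def fuse_overlaps(regions: Sequence[GenomicInterval],
                  merge_adjacent: bool = False) -> list[GenomicInterval]:
    """Merge strictly overlapping regions into their union.

    Bookended (merely adjacent) regions are kept separate unless
    ``merge_adjacent`` is set.  Output is sorted by (chrom, start) and
    covers exactly the same bases as the input.
    """
    if not regions:
        return []
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    fused: list[GenomicInterval] = []
    cur = ordered[0]
    for r in ordered[1:]:
        joins = (r.chrom == cur.chrom
                 and (r.start < cur.end if not merge_adjacent
                      else r.start <= cur.end))
        if joins:
            if r.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, r.end)
        else:
            fused.append(GenomicInterval(cur.chrom, cur.start, cur.end))
            cur = r
    fused.append(GenomicInterval(cur.chrom, cur.start, cur.end))
    return fused


def subtract_exclusions(regions: Sequence[GenomicInterval],
                        exclusions: Sequence[GenomicInterval],
                        ) -> list[GenomicInterval]:
    """Subtract a user-supplied exclusion set (e.g. repeat intervals)."""
    out = []
    for r in regions:
        pieces = [(r.start, r.end)]
        for x in exclusions:
            if x.chrom != r.chrom:
                continue
            nxt = []
            for lo, hi in pieces:
                if x.end <= lo or hi <= x.start:
                    nxt.append((lo, hi))
                    continue
                if lo < x.start:
                    nxt.append((lo, x.start))
                if x.end < hi:
                    nxt.append((x.end, hi))
            pieces = nxt
        out.extend(GenomicInterval(r.chrom, lo, hi) for lo, hi in pieces)
    return out


def summarize_design(regions: Sequence[GenomicInterval],
                     genes: Sequence[GeneModel]) -> TargetDesign:
    """Summarise a fused region set.

    ``coding_bases`` counts target bases lying in any gene's CDS — the
    class-precedence rule puts CDS first, so membership in any CDS
    segment decides.
    """
    ordered = tuple(sorted(regions, key=lambda r: (r.chrom, r.start)))
    cds_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        cds_by_chrom.setdefault(g.chrom, []).extend(g.cds_segments())
    coding = 0
    for r in ordered:
        segs = cds_by_chrom.get(r.chrom, ())
        if not segs:
            continue
        covered = np.zeros(len(r), dtype=bool)
        for s, e in segs:
            lo, hi = max(s, r.start), min(e, r.end)
            if lo < hi:
                covered[lo - r.start:hi - r.start] = True
        coding += int(covered.sum())
    total = sum(len(r) for r in ordered)
    return TargetDesign(regions=ordered, n_regions=len(ordered),
                        total_bases=total, coding_bases=coding)


def design_targets(genes: Sequence[GeneModel],
                   chrom_lengths: Mapping[str, int],
                   promoter_len: int = DEFAULT_PROMOTER_LEN,
                   min_len: int = DEFAULT_MIN_REGION_LEN,
                   exclusions: Sequence[GenomicInterval] = (),
                   merge_adjacent: bool = False) -> TargetDesign:
    """Full design pipeline: extract → pad → fuse (→ subtract) → summarize."""
    raw = extract_raw_regions(genes, promoter_len, chrom_lengths)
    padded = pad_regions(raw, min_len, chrom_lengths)
    fused = fuse_overlaps(padded, merge_adjacent=merge_adjacent)
    if exclusions:
        fused = fuse_overlaps(subtract_exclusions(fused, exclusions),
                              merge_adjacent=merge_adjacent)
    logger.info("target design: %d raw -> %d fused regions", len(raw), len(fused))
    return summarize_design(fused, genes)


def write_design_summary(path: str | Path, design: TargetDesign) -> None:
    pd.DataFrame([{"n_regions": design.n_regions,
                   "total_bases": design.total_bases,
                   "coding_bases": design.coding_bases}]
                 ).to_csv(path, sep="\t", index=False)
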