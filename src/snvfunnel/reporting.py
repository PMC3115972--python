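"""Summary surfaces: per-sample coverage, per-base variation rates, the
candidate funnel, and the false-positive rate.

Conventions adopted throughout: mean coverage = mapped bases / target
bases, rounded half away from zero to an integer; per-base variation
rates are per-sample averages (total calls divided by the number of
samples, then by the base count of the compartment), as percent to two
decimals, rounded half away from zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .gene_models import RegionClass
from .variant_pipeline import AnnotatedVariant

logger = logging.getLogger("snvfunnel")

_EXONIC = (RegionClass.CDS, RegionClass.UTR5, RegionClass.UTR3)
_IN_GENE = _EXONIC + (RegionClass.PROMOTER, RegionClass.INTRON)


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoverageRow:
    sample_id: str
    mapped_reads: int
    mapped_bases: int
    mean_coverage: int
    snv_count: int
    coding_snv_count: int

    def __post_init__(self) -> None:
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")
        if self.coding_snv_count > self.snv_count:
            raise ValueError("coding_snv_count exceeds snv_count")


@dataclass(frozen=True)
class FunnelCounts:
    """The candidate funnel (filter cascade) over unique variants.

    Position rows (``unique_positions_total`` down to
    ``non_synonymous_in_cds``) count unique (chrom, pos) positions;
    novelty rows count unique (chrom, pos, ref, alt) keys.  Verified
    counts are ``None`` while verification is untested.  Promoter-class
    positions are in target genes but neither exonic nor intronic, so
    ``in_exons_incl_utr + in_introns`` can fall short of
    ``in_target_genes`` by exactly the promoter-position count.
    """

    unique_positions_total: int
    in_target_genes: int
    in_exons_incl_utr: int
    in_introns: int
    in_cds: int
    in_non_coding: int
    non_synonymous_in_cds: int
    novel_non_synonymous: int
    verified_novel: int | None
    novel_recurrent: int
    verified_novel_recurrent: int | None

    def validate(self) -> None:
        if self.in_cds + self.in_non_coding != self.unique_positions_total:
            raise ValueError("in_cds + in_non_coding != total positions")
        if self.in_exons_incl_utr + self.in_introns > self.in_target_genes:
            raise ValueError("exon + intron positions exceed in-gene positions")
        if self.in_target_genes > self.unique_positions_total:
            raise ValueError("in_target_genes exceeds total positions")
        if self.non_synonymous_in_cds > self.in_cds:
            raise ValueError("non-synonymous positions exceed CDS positions")
        if self.verified_novel is not None and \
                self.verified_novel > self.novel_non_synonymous:
            raise ValueError("verified_novel exceeds novel_non_synonymous")
        if self.novel_recurrent > self.novel_non_synonymous:
            raise ValueError("novel_recurrent exceeds novel_non_synonymous")
        if self.verified_novel_recurrent is not None:
            if self.verified_novel is None:
                raise ValueError("verified_novel_recurrent without verified_novel")
            if self.verified_novel_recurrent > min(self.verified_novel,
                                                   self.novel_recurrent):
                raise ValueError("verified_novel_recurrent exceeds bound")


def coverage_table(tallies: Sequence[Mapping], target_bases: int
                   ) -> tuple[list[CoverageRow], CoverageRow]:
    """Per-sample coverage rows plus a pooled total row.

    Each tally needs ``sample_id``, ``mapped_reads``, ``mapped_bases``,
    ``snv_count`` and ``coding_snv_count``.  The total row sums the
    additive columns and computes pooled coverage from summed bases.
    """
    if target_bases <= 0:
        raise ValueError("target_bases must be > 0")
    rows = []
    for t in tallies:
        rows.append(CoverageRow(
            sample_id=t["sample_id"],
            mapped_reads=int(t["mapped_reads"]),
            mapped_bases=int(t["mapped_bases"]),
            mean_coverage=int(_round_half_up(t["mapped_bases"] / target_bases)),
            snv_count=int(t["snv_count"]),
            coding_snv_count=int(t["coding_snv_count"])))
    total_bases = sum(r.mapped_bases for r in rows)
    total = CoverageRow(
        sample_id="Total",
        mapped_reads=sum(r.mapped_reads for r in rows),
        mapped_bases=total_bases,
        mean_coverage=int(_round_half_up(total_bases / target_bases)),
        snv_count=sum(r.snv_count for r in rows),
        coding_snv_count=sum(r.coding_snv_count for r in rows))
    return rows, total


def variation_rates(total_snvs: int, coding_snvs: int, n_samples: int,
                    total_bases: int, coding_bases: int
                    ) -> tuple[float, float]:
    """Per-sample-average per-base variation rates, in percent (2 dp).

    The non-coding rate divides the per-sample average of non-coding
    calls by the non-coding base count; likewise for coding.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if coding_bases >= total_bases:
        raise ValueError("coding_bases must be < total_bases")
    if coding_snvs > total_snvs:
        raise ValueError("coding_snvs exceeds total_snvs")
    noncoding_rate = ((total_snvs - coding_snvs) / n_samples) \
        / (total_bases - coding_bases) * 100
    coding_rate = (coding_snvs / n_samples) / coding_bases * 100
    return _round_half_up(noncoding_rate, 2), _round_half_up(coding_rate, 2)


def build_funnel(variants: Sequence[AnnotatedVariant]) -> FunnelCounts:
    """Candidate funnel over annotated unique variants.

    Requires novelty and recurrence to be populated; verification may be
    untested, in which case the verified rows are ``None``.  Variants
    flagged unannotatable (broken CDS frame) count as non-coding.
    """
    for v in variants:
        v.validate()
        if v.novel is None:
            raise ValueError(f"{v.key}: novelty not populated")

    # position rows: group by (chrom, pos); CDS membership additionally
    # requires an annotatable CDS variant at the position
    by_pos: dict[tuple[str, int], list[AnnotatedVariant]] = {}
    for v in variants:
        by_pos.setdefault((v.chrom, v.pos), []).append(v)
    n_total = len(by_pos)
    n_gene = n_exon = n_intron = n_cds = n_nonsyn = 0
    for vs in by_pos.values():
        classes = {v.region_class for v in vs}
        cds = any(v.region_class is RegionClass.CDS and v.annotatable
                  for v in vs)
        if any(c in _IN_GENE for c in classes):
            n_gene += 1
        if any(c in _EXONIC for c in classes):
            n_exon += 1
        elif RegionClass.INTRON in classes:
            n_intron += 1
        if cds:
            n_cds += 1
            if any(v.effect == "non_synonymous" for v in vs):
                n_nonsyn += 1

    novel_nonsyn = [v for v in variants
                    if v.novel and v.effect == "non_synonymous"]
    any_untested = any(v.verification == "untested" for v in novel_nonsyn)
    verified = None if any_untested else \
        sum(1 for v in novel_nonsyn if v.verification == "verified")
    recurrent = [v for v in novel_nonsyn if v.n_samples > 1]
    verified_recurrent = None if any_untested else \
        sum(1 for v in recurrent if v.verification == "verified")

    funnel = FunnelCounts(
        unique_positions_total=n_total,
        in_target_genes=n_gene,
        in_exons_incl_utr=n_exon,
        in_introns=n_intron,
        in_cds=n_cds,
        in_non_coding=n_total - n_cds,
        non_synonymous_in_cds=n_nonsyn,
        novel_non_synonymous=len(novel_nonsyn),
        verified_novel=verified,
        novel_recurrent=len(recurrent),
        verified_novel_recurrent=verified_recurrent)
    funnel.validate()
    return funnel


def false_positive_rate(n_candidates: int, n_verified: int) -> float:
    """Percentage of verification candidates refuted by the oracle."""
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    if not 0 <= n_verified <= n_candidates:
        raise ValueError("n_verified out of range")
    return 100.0 * (n_candidates - n_verified) / n_candidates


# -- rendering --------------------------------------------------------------

_FUNNEL_LABELS = [
    ("unique_positions_total", "Total unique positions with SNVs"),
    ("in_target_genes", "In target genes"),
    ("in_exons_incl_utr", "In exons (incl UTR)"),
    ("in_introns", "In introns"),
    ("in_cds", "In coding sequence (CDS)"),
    ("in_non_coding", "In non-coding sequence"),
    ("non_synonymous_in_cds", "Non-synonymous in CDS"),
    ("novel_non_synonymous", "Novel non-synonymous not in catalog"),
    ("verified_novel", "Verified novel non-synonymous"),
    ("novel_recurrent", "Novel non-synonymous in >1 sample"),
    ("verified_novel_recurrent", "Verified novel non-synonymous in >1 sample"),
]


def coverage_dataframe(rows: Sequence[CoverageRow],
                       total: CoverageRow) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in [*rows, total]])


def funnel_dataframe(funnel: FunnelCounts) -> pd.DataFrame:
    return pd.DataFrame(
        [{"stage": label,
          "count": getattr(funnel, attr) if getattr(funnel, attr) is not None
          else "untested"}
         for attr, label in _FUNNEL_LABELS])


def render_report(rows: Sequence[CoverageRow], total: CoverageRow,
                  funnel: FunnelCounts, rates: tuple[float, float],
                  fp_rate: float | None) -> str:
    lines = ["Per-sample coverage", "-" * 19,
             coverage_dataframe(rows, total).to_string(index=False), "",
             "Variation rates (% per base, per-sample average)",
             f"  non-coding: {rates[0]:.2f}%",
             f"  coding:     {rates[1]:.2f}%", "",
             "Candidate funnel", "-" * 16,
             funnel_dataframe(funnel).to_string(index=False)]
    if fp_rate is not None:
        lines += ["", f"False positive rate among verified candidates: "
                      f"{fp_rate:.1f}%"]
    return "\n".join(lines) + "\n"


def write_report(path: str | Path, rows: Sequence[CoverageRow],
                 total: CoverageRow, funnel: FunnelCounts,
                 rates: tuple[float, float], fp_rate: float | None) -> None:
    Path(path).write_text(render_report(rows, total, funnel, rates, fp_rate))


def plot_coverage_histogram(rows: Sequence[CoverageRow], path: str | Path
                            ) -> None:
    """Bar chart of per-sample mean coverage."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar([r.sample_id for r in rows], [r.mean_coverage for r in rows])
    ax.set_ylabel("mean coverage (x)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
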