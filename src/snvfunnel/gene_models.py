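"""Genomic coordinate types, annotation I/O and region classification.

All internal coordinates are 0-based half-open.  BED output stays 0-based
half-open; VCF output is converted to 1-based at the I/O boundary only.

A gene model carries transcript bounds, an ordered disjoint exon list and
CDS bounds; every base of a chromosome falls into exactly one of six
region classes relative to a gene (promoter, 5'UTR, CDS, intron, 3'UTR,
intergenic).  The promoter is the fixed-length window strand-upstream of
the transcript start, i.e. upstream of the 5'UTR.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("snvfunnel")

VALID_BASES = frozenset("ACGTN")
DEFAULT_PROMOTER_LEN = 1000


class ValidationError(ValueError):
    """An object violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed in the declared dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class RegionClass(enum.Enum):
    """Functional class of a genomic position relative to a gene.

    ``precedence`` resolves positions claimed by overlapping genes: the
    most consequence-bearing class wins (CDS > UTR5 > UTR3 > PROMOTER >
    INTRON > INTERGENIC).
    """

    CDS = "CDS"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    PROMOTER = "PROMOTER"
    INTRON = "INTRON"
    INTERGENIC = "INTERGENIC"

    @property
    def precedence(self) -> int:
        return _PRECEDENCE[self]


_PRECEDENCE = {
    RegionClass.CDS: 0,
    RegionClass.UTR5: 1,
    RegionClass.UTR3: 2,
    RegionClass.PROMOTER: 3,
    RegionClass.INTRON: 4,
    RegionClass.INTERGENIC: 5,
}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strict overlap (shared bases); bookended intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GeneModel:
    """A single-transcript gene model with exons and CDS bounds."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValidationError(f"{self.gene_id}: invalid transcript bounds")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValidationError(
                    f"{self.gene_id}: exon [{s},{e}) outside transcript span"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"{self.gene_id}: exons unsorted or overlapping at [{s},{e})"
                )
            prev_end = e
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: no exons")
        if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
            raise ValidationError(f"{self.gene_id}: CDS bounds outside transcript")
        if not any(s <= self.cds_start < e for s, e in self.exons):
            raise ValidationError(f"{self.gene_id}: cds_start not exonic")
        if not any(s < self.cds_end <= e for s, e in self.exons):
            raise ValidationError(f"{self.gene_id}: cds_end not exonic")

    # -- derived geometry ---------------------------------------------------

    def cds_segments(self) -> list[tuple[int, int]]:
        """Genomic CDS segments: exon pieces clipped to [cds_start, cds_end)."""
        segs = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo < hi:
                segs.append((lo, hi))
        return segs

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments())

    def cds_frame_ok(self) -> bool:
        return self.cds_length() % 3 == 0

    def promoter_interval(self, promoter_len: int = DEFAULT_PROMOTER_LEN,
                          chrom_length: int | None = None) -> tuple[int, int] | None:
        """Strand-upstream promoter window, clamped at chromosome bounds.

        Returns ``None`` when the window is entirely off-chromosome.
        """
        if self.strand == "+":
            lo, hi = self.tx_start - promoter_len, self.tx_start
        else:
            lo, hi = self.tx_end, self.tx_end + promoter_len
        lo = max(lo, 0)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        if lo >= hi:
            return None
        return lo, hi


class ReferenceGenome(dict):
    """Mapping of chromosome name to uppercase nucleotide string.

    Sequences are canonicalised to uppercase; only A/C/G/T/N are allowed.
    """

    def __setitem__(self, chrom: str, seq: str) -> None:
        seq = seq.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValidationError(f"{chrom}: invalid bases {sorted(bad)}")
        super().__setitem__(chrom, seq)

    def length(self, chrom: str) -> int:
        return len(self[chrom])

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.items()}

    def validate_genes(self, genes: Iterable[GeneModel],
                       promoter_len: int = 0) -> None:
        for g in genes:
            if g.chrom not in self:
                raise ValidationError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.tx_end > self.length(g.chrom):
                raise ValidationError(f"{g.gene_id}: transcript past chromosome end")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_position(gene: GeneModel, pos: int,
                      promoter_len: int = DEFAULT_PROMOTER_LEN) -> RegionClass:
    """Classify ``pos`` relative to ``gene``.

    Total over valid positions: returns exactly one class.  UTR5/UTR3 are
    strand-aware (the 5' UTR sits before the CDS in transcription order).
    """
    prom = gene.promoter_interval(promoter_len)
    if prom is not None and prom[0] <= pos < prom[1]:
        # the promoter window never overlaps the transcript span itself
        if not (gene.tx_start <= pos < gene.tx_end):
            return RegionClass.PROMOTER
    if gene.tx_start <= pos < gene.tx_end:
        exonic = any(s <= pos < e for s, e in gene.exons)
        if not exonic:
            return RegionClass.INTRON
        if gene.cds_start <= pos < gene.cds_end:
            return RegionClass.CDS
        if pos < gene.cds_start:
            return RegionClass.UTR5 if gene.strand == "+" else RegionClass.UTR3
        return RegionClass.UTR3 if gene.strand == "+" else RegionClass.UTR5
    return RegionClass.INTERGENIC


def classify_site(genes: Sequence[GeneModel], chrom: str, pos: int,
                  promoter_len: int = DEFAULT_PROMOTER_LEN,
                  ) -> tuple[RegionClass, GeneModel | None]:
    """Pipeline-level class of a site under the class-precedence rule.

    Each gene classifies the position independently; the most
    consequence-bearing class wins.  Ties break on gene_id for determinism.
    """
    best: tuple[int, str] | None = None
    best_cls, best_gene = RegionClass.INTERGENIC, None
    for g in genes:
        if g.chrom != chrom:
            continue
        cls = classify_position(g, pos, promoter_len)
        key = (cls.precedence, g.gene_id)
        if cls is not RegionClass.INTERGENIC and (best is None or key < best):
            best, best_cls, best_gene = key, cls, g
    return best_cls, best_gene


def cds_coordinates(gene: GeneModel, pos: int) -> tuple[int, int, int]:
    """Spliced-CDS coordinates of a genomic CDS position.

    Returns ``(cds_index, codon_number, position_in_codon)`` where
    ``cds_index`` counts from the strand-aware translation start, so
    ``cds_index = 3 * codon_number + position_in_codon``.
    """
    if classify_position(gene, pos) is not RegionClass.CDS:
        raise ValueError(f"{gene.gene_id}: position {pos} is not in the CDS")
    offset = 0
    plus_index = None
    for s, e in gene.cds_segments():
        if s <= pos < e:
            plus_index = offset + (pos - s)
            break
        offset += e - s
    assert plus_index is not None
    total = gene.cds_length()
    idx = plus_index if gene.strand == "+" else total - 1 - plus_index
    return idx, idx // 3, idx % 3


def spliced_cds_sequence(gene: GeneModel, genome: ReferenceGenome) -> str:
    """Spliced CDS in translation (5'→3') orientation."""
    seq = "".join(genome[gene.chrom][s:e] for s, e in gene.cds_segments())
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> ReferenceGenome:
    genome = ReferenceGenome()
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq)
    if not genome:
        raise ParseError(f"{path}: no FASTA records")
    return genome


def write_fasta(path: str | Path, genome: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene-model I/O: tab-delimited gene table and a GFF3 subset
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["gene_id", "chrom", "strand", "tx_start", "tx_end",
                  "exon_starts", "exon_ends", "cds_start", "cds_end"]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a gene-table TSV or a GFF3-subset file.

    The dialect is chosen by extension (``.gff``/``.gff3`` vs anything
    else).  Input order is preserved; every model is validated.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    return _read_gene_table(path)


def write_gene_models(path: str | Path, genes: Sequence[GeneModel]) -> None:
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        _write_gff3(path, genes)
    else:
        _write_gene_table(path, genes)


def _read_gene_table(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TABLE_COLUMNS:
            raise ParseError(f"{path}:1: bad gene-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_TABLE_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected "
                                 f"{len(_TABLE_COLUMNS)} fields, got {len(fields)}")
            try:
                starts = [int(x) for x in fields[5].split(",")]
                ends = [int(x) for x in fields[6].split(",")]
                gene = GeneModel(
                    gene_id=fields[0], chrom=fields[1], strand=fields[2],
                    tx_start=int(fields[3]), tx_end=int(fields[4]),
                    exons=list(zip(starts, ends)),
                    cds_start=int(fields[7]), cds_end=int(fields[8]),
                )
            except ValidationError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(starts) != len(ends):
                raise ParseError(f"{path}:{lineno}: exon_starts/exon_ends length mismatch")
            genes.append(gene)
    return genes


def _write_gene_table(path: Path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write("\t".join([
                g.gene_id, g.chrom, g.strand, str(g.tx_start), str(g.tx_end),
                ",".join(str(s) for s, _ in g.exons),
                ",".join(str(e) for _, e in g.exons),
                str(g.cds_start), str(g.cds_end),
            ]) + "\n")


def _read_gff3(path: Path) -> list[GeneModel]:
    """Parse the documented GFF3 subset: gene / exon / CDS features only.

    GFF3 is 1-based inclusive on disk; coordinates are converted to
    0-based half-open here and nowhere else.
    """
    order: list[str] = []
    raw: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene without ID")
                order.append(gid)
                raw[gid] = {"chrom": chrom, "strand": strand,
                            "tx": (start0, end0), "exons": [], "cds": []}
            elif ftype in ("exon", "CDS"):
                gid = attr.get("Parent")
                if gid is None or gid not in raw:
                    raise ParseError(f"{path}:{lineno}: {ftype} with unknown Parent")
                raw[gid]["exons" if ftype == "exon" else "cds"].append((start0, end0))
            else:
                raise ParseError(f"{path}:{lineno}: unsupported feature {ftype!r}")
    genes = []
    for gid in order:
        r = raw[gid]
        if not r["cds"]:
            raise ParseError(f"{path}: gene {gid} has no CDS features")
        genes.append(GeneModel(
            gene_id=gid, chrom=r["chrom"], strand=r["strand"],
            tx_start=r["tx"][0], tx_end=r["tx"][1],
            exons=sorted(r["exons"]),
            cds_start=min(s for s, _ in r["cds"]),
            cds_end=max(e for _, e in r["cds"]),
        ))
    return genes


def _write_gff3(path: Path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([g.chrom, "snvfunnel", "gene",
                                str(g.tx_start + 1), str(g.tx_end), ".",
                                g.strand, ".", f"ID={g.gene_id}"]) + "\n")
            for s, e in g.exons:
                fh.write("\t".join([g.chrom, "snvfunnel", "exon",
                                    str(s + 1), str(e), ".", g.strand, ".",
                                    f"Parent={g.gene_id}"]) + "\n")
            for s, e in g.cds_segments():
                fh.write("\t".join([g.chrom, "snvfunnel", "CDS",
                                    str(s + 1), str(e), ".", g.strand, ".",
                                    f"Parent={g.gene_id}"]) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(path: str | Path, intervals: Sequence[GenomicInterval],
              name_prefix: str = "region") -> None:
    """BED6 writer; coordinates stay 0-based half-open."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                     f"{name_prefix}{i + 1}\t0\t{iv.strand if iv.strand != '.' else '.'}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected ≥3 BED columns")
            strand = f[5] if len(f) >= 6 else "."
            intervals.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return intervals
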