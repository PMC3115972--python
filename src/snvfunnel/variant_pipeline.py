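"""Multiplexed per-sample SNV calling, annotation and the candidate funnel.

Reads carry a multiplex identifier (MID) barcode tag and their true
genomic origin, so the pipeline demultiplexes by exact tag match, tallies
per-sample per-position base counts over the capture target (no aligner
is involved), and emits a variant call wherever an alternative allele
passes a strict allele-fraction threshold at sufficient depth.  Calls are
then annotated for region class and amino-acid effect, flagged for
novelty against a known-variant catalog, counted across samples
(recurrence), and finally confronted with an orthogonal verification
oracle standing in for bidirectional Sanger sequencing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .gene_models import (
    DEFAULT_PROMOTER_LEN,
    GeneModel,
    ReferenceGenome,
    RegionClass,
    cds_coordinates,
    classify_site,
    spliced_cds_sequence,
)
from .target_design import TargetDesign

logger = logging.getLogger("snvfunnel")

DEFAULT_MIN_FRACTION = 0.20  # strict: a call needs alt_fraction ABOVE this
DEFAULT_MIN_DEPTH = 5

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CODE[ord(_b)] = _i

VariantKey = tuple[str, int, str, str]  # (chrom, pos, ref, alt)


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3; anything else (N) as -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarcodedRead:
    read_id: str
    mid: str
    chrom: str
    start: int
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGTN"):
            raise ValueError(f"{self.read_id}: invalid sequence")


@dataclass(frozen=True)
class SnvCall:
    sample_id: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.alt_base == self.ref_base:
            raise ValueError("alt equals ref")

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref_base, self.alt_base)


@dataclass
class AnnotatedVariant:
    """One unique (chrom, pos, ref, alt) variant with its annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    region_class: RegionClass
    effect: str  # synonymous | non_synonymous | non_coding
    gene_id: str | None = None
    aa_change: tuple[str, int, str] | None = None  # (refAA, codon_number, altAA)
    novel: bool | None = None
    n_samples: int = 1
    verification: str = "untested"  # untested | verified | false_positive
    annotatable: bool = True

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    def validate(self) -> None:
        in_cds = self.region_class is RegionClass.CDS and self.annotatable
        if in_cds != (self.effect in ("synonymous", "non_synonymous")):
            raise ValueError(
                f"{self.key}: effect {self.effect!r} inconsistent with "
                f"region class {self.region_class.value}")
        if self.n_samples < 1:
            raise ValueError(f"{self.key}: n_samples must be >= 1")


class Pileup:
    """Per-sample per-position base counts restricted to the target design."""

    def __init__(self, sample_ids: Sequence[str],
                 chrom_lengths: Mapping[str, int],
                 target_masks: Mapping[str, np.ndarray]) -> None:
        self.sample_ids = list(sample_ids)
        self.chrom_lengths = dict(chrom_lengths)
        self.target_masks = {c: np.asarray(m, dtype=bool)
                             for c, m in target_masks.items()}
        self.counts: dict[str, dict[str, np.ndarray]] = {
            s: {c: np.zeros((4, n), dtype=np.int32)
                for c, n in chrom_lengths.items()}
            for s in sample_ids
        }
        # bookkeeping for the coverage report
        self.reads_on_target: dict[str, int] = {s: 0 for s in sample_ids}
        self.bases_on_target: dict[str, int] = {s: 0 for s in sample_ids}

    def add_read(self, sample: str, chrom: str, start: int, seq: str) -> None:
        clen = self.chrom_lengths[chrom]
        if start + len(seq) > clen:
            logger.warning("read at %s:%d extends past chromosome end; truncated",
                           chrom, start)
            seq = seq[:clen - start]
        if not seq:
            return
        codes = seq_to_codes(seq)
        idx = np.arange(start, start + len(seq))
        keep = (codes >= 0) & self.target_masks[chrom][idx]
        n_kept = int(keep.sum())
        if n_kept == 0:
            return
        np.add.at(self.counts[sample][chrom], (codes[keep], idx[keep]), 1)
        self.reads_on_target[sample] += 1
        self.bases_on_target[sample] += n_kept

    def depth(self, sample: str, chrom: str, pos: int) -> int:
        return int(self.counts[sample][chrom][:, pos].sum())

    def base_counts(self, sample: str, chrom: str, pos: int) -> dict[str, int]:
        col = self.counts[sample][chrom][:, pos]
        return {b: int(col[i]) for b, i in BASE_INDEX.items()}


def build_pileup(reads_by_sample: Mapping[str, Sequence[BarcodedRead]],
                 genome: ReferenceGenome,
                 design: TargetDesign) -> Pileup:
    """Tally origin-annotated reads into a target-restricted pileup."""
    masks = design.chrom_masks(genome.lengths())
    pileup = Pileup(list(reads_by_sample), genome.lengths(), masks)
    for sample, reads in reads_by_sample.items():
        for r in reads:
            if r.chrom not in genome:
                raise ValueError(f"{r.read_id}: unknown chromosome {r.chrom}")
            pileup.add_read(sample, r.chrom, r.start, r.sequence)
    return pileup


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def demultiplex(reads: Iterable[BarcodedRead], mids: Sequence[str]
                ) -> dict[str, list[BarcodedRead]]:
    """Assign reads to samples by exact barcode-tag match.

    Returns one bin per MID plus an ``"unassigned"`` bin; every input read
    lands in exactly one bin.
    """
    mids = list(mids)
    if len(set(mids)) != len(mids):
        raise ValueError("duplicate barcode in MID set")
    bins: dict[str, list[BarcodedRead]] = {m: [] for m in mids}
    bins["unassigned"] = []
    known = set(mids)
    for r in reads:
        bins[r.mid if r.mid in known else "unassigned"].append(r)
    return bins


# ---------------------------------------------------------------------------
# SNV calling
# ---------------------------------------------------------------------------

def call_snvs(pileup: Pileup, genome: ReferenceGenome,
              min_fraction: float = DEFAULT_MIN_FRACTION,
              min_depth: int = DEFAULT_MIN_DEPTH) -> list[SnvCall]:
    """Emit a call for every (sample, position, alt) with depth >= min_depth
    and alt_count/depth strictly above ``min_fraction``.

    Multiple alternative alleles at one position each yield their own
    call.  Positions whose reference base is N are skipped.
    """
    calls: list[SnvCall] = []
    ref_codes = {c: seq_to_codes(seq) for c, seq in genome.items()}
    n_skipped = 0
    for sample in pileup.sample_ids:
        for chrom in sorted(pileup.counts[sample]):
            counts = pileup.counts[sample][chrom]
            depth = counts.sum(axis=0)
            mask = pileup.target_masks[chrom] & (depth >= min_depth)
            n_skipped += int((mask & (ref_codes[chrom] < 0)).sum())
            mask &= ref_codes[chrom] >= 0
            positions = np.flatnonzero(mask)
            refc = ref_codes[chrom][positions]
            d = depth[positions].astype(np.float64)
            for b in range(4):
                alt = counts[b, positions]
                hit = (alt / d > min_fraction) & (refc != b)
                for pos, dd, ac in zip(positions[hit],
                                       depth[positions][hit], alt[hit]):
                    calls.append(SnvCall(
                        sample_id=sample, chrom=chrom, pos=int(pos),
                        ref_base=BASES[ref_codes[chrom][pos]],
                        alt_base=BASES[b], depth=int(dd), alt_count=int(ac)))
    if n_skipped:
        logger.info("call_snvs: skipped %d covered positions with N reference",
                    n_skipped)
    calls.sort(key=lambda c: (c.chrom, c.pos, c.alt_base, c.sample_id))
    return calls


# ---------------------------------------------------------------------------
# Effect annotation
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def annotate_variant(call: SnvCall, genes: Sequence[GeneModel],
                     genome: ReferenceGenome,
                     promoter_len: int = DEFAULT_PROMOTER_LEN,
                     ) -> AnnotatedVariant:
    """Region class and amino-acid effect of one call.

    For CDS calls the affected codon is rebuilt strand-aware from the
    spliced CDS and translated with the standard nuclear code; the effect
    is synonymous iff the amino acid is unchanged.  Genes whose spliced
    CDS length is not divisible by 3 cannot be annotated: the variant is
    flagged unannotatable and excluded from CDS counts.
    """
    if call.chrom not in genome:
        raise ValueError(f"unknown chromosome {call.chrom}")
    cls, gene = classify_site(genes, call.chrom, call.pos, promoter_len)
    if cls is not RegionClass.CDS:
        return AnnotatedVariant(call.chrom, call.pos, call.ref_base,
                                call.alt_base, region_class=cls,
                                effect="non_coding",
                                gene_id=gene.gene_id if gene else None)
    assert gene is not None
    if not gene.cds_frame_ok():
        logger.warning("gene %s: CDS length %d not divisible by 3; variant "
                       "%s:%d unannotatable", gene.gene_id, gene.cds_length(),
                       call.chrom, call.pos)
        return AnnotatedVariant(call.chrom, call.pos, call.ref_base,
                                call.alt_base, region_class=cls,
                                effect="non_coding", gene_id=gene.gene_id,
                                annotatable=False)
    cds_index, codon_number, pos_in_codon = cds_coordinates(gene, call.pos)
    cds_seq = spliced_cds_sequence(gene, genome)
    codon = cds_seq[3 * codon_number:3 * codon_number + 3]
    ref_base = call.ref_base if gene.strand == "+" else \
        call.ref_base.translate(_COMPLEMENT)
    alt_base = call.alt_base if gene.strand == "+" else \
        call.alt_base.translate(_COMPLEMENT)
    if codon[pos_in_codon] != ref_base:
        raise ValueError(
            f"{call.chrom}:{call.pos}: reference base mismatch in codon "
            f"({codon!r}[{pos_in_codon}] != {ref_base!r})")
    mutated = codon[:pos_in_codon] + alt_base + codon[pos_in_codon + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutated).translate())
    effect = "synonymous" if ref_aa == alt_aa else "non_synonymous"
    return AnnotatedVariant(call.chrom, call.pos, call.ref_base, call.alt_base,
                            region_class=cls, effect=effect,
                            gene_id=gene.gene_id,
                            aa_change=(ref_aa, codon_number, alt_aa))


def translate_cds_with_variant(gene: GeneModel, genome: ReferenceGenome,
                               pos: int, alt: str) -> str:
    """Translate the entire CDS with one substituted base (full-protein
    oracle for the single-codon shortcut)."""
    idx, _, _ = cds_coordinates(gene, pos)
    cds = spliced_cds_sequence(gene, genome)
    base = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
    mutated = cds[:idx] + base + cds[idx + 1:]
    return str(Seq(mutated).translate())


# ---------------------------------------------------------------------------
# Novelty, recurrence, verification
# ---------------------------------------------------------------------------

def flag_novelty(variants: Sequence[AnnotatedVariant],
                 catalog: Iterable, genome: ReferenceGenome | None = None,
                 match_mode: str = "site") -> list[AnnotatedVariant]:
    """Set ``novel`` on every variant: True iff absent from the catalog.

    ``match_mode='site'`` keys the catalog by (chrom, pos, ref, alt);
    ``'position'`` by (chrom, pos) only (dbSNP-era positional matching).
    """
    if match_mode not in ("site", "position"):
        raise ValueError(f"unknown match_mode {match_mode!r}")
    keys = set()
    for entry in catalog:
        chrom, pos = entry[0], entry[1]
        if genome is not None and len(entry) >= 3:
            ref = entry[2]
            if genome[chrom][pos] != ref:
                logger.warning("catalog entry %s:%d ref %s mismatches genome "
                               "%s; entry kept", chrom, pos, ref,
                               genome[chrom][pos])
        keys.add((chrom, pos) if match_mode == "position" else tuple(entry[:4]))
    out = []
    for v in variants:
        probe = (v.chrom, v.pos) if match_mode == "position" else v.key
        out.append(replace_fields(v, novel=probe not in keys))
    return out


def replace_fields(v: AnnotatedVariant, **kw) -> AnnotatedVariant:
    d = dict(v.__dict__)
    d.update(kw)
    return AnnotatedVariant(**d)


def compute_recurrence(calls: Sequence[SnvCall]) -> dict[VariantKey, int]:
    """Number of distinct samples carrying each (chrom,pos,ref,alt) key."""
    samples: dict[VariantKey, set[str]] = {}
    for c in calls:
        samples.setdefault(c.key, set()).add(c.sample_id)
    return {k: len(s) for k, s in samples.items()}


def apply_recurrence(variants: Sequence[AnnotatedVariant],
                     recurrence: Mapping[VariantKey, int]
                     ) -> list[AnnotatedVariant]:
    return [replace_fields(v, n_samples=recurrence.get(v.key, 1))
            for v in variants]


def verify_candidates(candidates: Sequence[AnnotatedVariant],
                      oracle: Callable[[VariantKey], str]
                      ) -> list[AnnotatedVariant]:
    """Set verification status from a total orthogonal-sequencing oracle.

    The oracle must return ``'verified'`` or ``'false_positive'`` for
    every candidate key; anything else is an error.
    """
    out = []
    for v in candidates:
        status = oracle(v.key)
        if status not in ("verified", "false_positive"):
            raise ValueError(f"oracle not total over candidates: {v.key} -> "
                             f"{status!r}")
        out.append(replace_fields(v, verification=status))
    return out


def unique_variants(calls: Sequence[SnvCall],
                    genes: Sequence[GeneModel],
                    genome: ReferenceGenome,
                    promoter_len: int = DEFAULT_PROMOTER_LEN,
                    ) -> list[AnnotatedVariant]:
    """Annotate the distinct variant keys of a call set (order-independent)."""
    seen: dict[VariantKey, SnvCall] = {}
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt_base)):
        seen.setdefault(c.key, c)
    return [annotate_variant(c, genes, genome, promoter_len)
            for c in seen.values()]


# ---------------------------------------------------------------------------
# Read / call / annotation I/O
# ---------------------------------------------------------------------------

_READ_COLUMNS = ["read_id", "mid", "chrom", "start", "sequence"]


def write_reads_tsv(path: str | Path, reads: Sequence[BarcodedRead]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_READ_COLUMNS) + "\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.mid}\t{r.chrom}\t{r.start}\t{r.sequence}\n")


def read_reads_tsv(path: str | Path) -> list[BarcodedRead]:
    reads = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _READ_COLUMNS:
            raise ValueError(f"{path}: bad reads header {header}")
        for line in fh:
            if not line.strip():
                continue
            rid, mid, chrom, start, seq = line.rstrip("\n").split("\t")
            reads.append(BarcodedRead(rid, mid, chrom, int(start), seq))
    return reads


def write_reads_fasta(path: str | Path, reads: Sequence[BarcodedRead]) -> None:
    """FASTA dialect: origin metadata in the description line."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id} mid={r.mid} chrom={r.chrom} start={r.start}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i:i + 60] + "\n")


def read_reads_fasta(path: str | Path) -> list[BarcodedRead]:
    from Bio import SeqIO
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = dict(kv.split("=", 1) for kv in rec.description.split()[1:]
                    if "=" in kv)
        reads.append(BarcodedRead(rec.id, meta["mid"], meta["chrom"],
                                  int(meta["start"]), str(rec.seq).upper()))
    return reads


def write_vcf(path: str | Path, calls: Sequence[SnvCall],
              genome: ReferenceGenome, sample_ids: Sequence[str]) -> None:
    """Minimal VCF export (1-based positions) with per-sample depth and
    allele fraction."""
    import pysam

    header = pysam.VariantHeader()
    for chrom, n in genome.lengths().items():
        header.contigs.add(chrom, length=n)
    header.add_line('##INFO=<ID=NS,Number=1,Type=Integer,'
                    'Description="Number of samples with the variant">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    header.add_line('##FORMAT=<ID=AF,Number=1,Type=Float,'
                    'Description="Alternative allele fraction">')
    for s in sample_ids:
        header.add_sample(s)
    by_key: dict[VariantKey, dict[str, SnvCall]] = {}
    for c in calls:
        by_key.setdefault(c.key, {})[c.sample_id] = c
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for key in sorted(by_key):
            chrom, pos, ref, alt = key
            rec = vf.new_record(contig=chrom, start=pos, stop=pos + 1,
                                alleles=(ref, alt))
            rec.info["NS"] = len(by_key[key])
            for s in sample_ids:
                c = by_key[key].get(s)
                if c is not None:
                    rec.samples[s]["DP"] = c.depth
                    rec.samples[s]["AF"] = round(c.alt_fraction, 4)
            vf.write(rec)


def write_annotations_tsv(path: str | Path,
                          variants: Sequence[AnnotatedVariant]) -> None:
    rows = []
    for v in variants:
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene_id": v.gene_id or ".",
            "region_class": v.region_class.value, "effect": v.effect,
            "aa_change": (f"{v.aa_change[0]}{v.aa_change[1] + 1}{v.aa_change[2]}"
                          if v.aa_change else "."),
            "novel": {True: "1", False: "0", None: "."}[v.novel],
            "n_samples": v.n_samples, "verification": v.verification,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path: str | Path) -> set[VariantKey]:
    """Known-variant catalog as TSV: chrom, pos (0-based), ref, alt."""
    out = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["chrom", "pos", "ref", "alt"]:
            raise ValueError(f"{path}: bad catalog header {header}")
        for line in fh:
            if line.strip():
                chrom, pos, ref, alt = line.rstrip("\n").split("\t")[:4]
                out.add((chrom, int(pos), ref, alt))
    return out


def write_catalog_tsv(path: str | Path, catalog: Iterable[VariantKey]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(catalog):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
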