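"""Synthetic study generator with a complete truth oracle.

Everything the pipeline consumes can be generated here at desk scale: a
small multi-gene genome, single-transcript gene models, an HPA-style
staining table whose qualifying proteins map onto the genes, per-sample
germline heterozygous variants planted at distinct coding and non-coding
densities, a known-variant catalog covering a configured fraction of the
planted variants, and barcoded reads for ten pooled sample libraries
with a deliberately uneven abundance profile (one near-dropout library
at ~3x and one underloaded at ~7x, mimicking a poorly amplified and an
underpooled multiplex tag).  A substitution-only uniform error process
plus a handful of "systematic error" sites with a boosted alternative
allele fraction reproduce the false-positive candidates that orthogonal
verification later refutes.

All randomness flows from a single seed through one numpy Generator, so
a fixed configuration is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .gene_models import GeneModel, GenomicInterval, ReferenceGenome
from .hpa_selection import StainingRecord
from .target_design import TargetDesign
from .variant_pipeline import (
    BASES,
    BarcodedRead,
    SnvCall,
    VariantKey,
    annotate_variant,
)

logger = logging.getLogger("snvfunnel")

# Table-1-like per-sample mean coverage profile: generally even, with one
# near-dropout library (~3x) and one underloaded library (~7x).
DEFAULT_COVERAGE = (33, 28, 3, 21, 28, 17, 18, 35, 7, 38)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic run.

    Densities are per base per sample; the coding density mirrors the
    ~0.05% per-base coding variation rate and the non-coding density the
    ~0.07% non-coding rate of a targeted tumor-panel study, so that at
    adequate coverage the recovered rates match the planted ones.
    """

    seed: int = 1
    n_chroms: int = 3
    chrom_length: int = 60_000
    n_genes: int = 18
    n_samples: int = 10
    mean_coverage: tuple = DEFAULT_COVERAGE
    read_length: int = 400
    error_rate: float = 0.001          # substitution probability per base
    coding_het_density: float = 0.0005
    noncoding_het_density: float = 0.0007
    recurrence_prob: float = 0.05      # chance a planted variant is shared
    catalog_fraction: float = 0.77     # planted variants present in catalog
    n_catalog_extra: int = 50          # catalog-only entries (never planted)
    n_systematic_sites: int = 6        # artifact sites -> false positives
    systematic_alt_fraction: float = 0.40
    off_target_fraction: float = 0.77  # fraction of reads off target
    promoter_len: int = 1000
    min_region_len: int = 250
    n_hpa_genes: int = 15              # genes selected via staining criteria
    n_decoy_proteins: int = 8          # staining-table proteins that fail
    somatic: bool = False              # reserved: all defaults are germline

    def __post_init__(self) -> None:
        rates = (self.error_rate, self.coding_het_density,
                 self.noncoding_het_density, self.recurrence_prob,
                 self.catalog_fraction, self.off_target_fraction,
                 self.systematic_alt_fraction)
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if len(self.mean_coverage) != self.n_samples:
            raise ValueError("mean_coverage length must equal n_samples")
        if any(c < 0 for c in self.mean_coverage):
            raise ValueError("coverage must be >= 0")
        if self.read_length < 1:
            raise ValueError("read length must be >= 1")
        if not 0 <= self.n_hpa_genes <= self.n_genes:
            raise ValueError("n_hpa_genes out of range")

    @property
    def sample_ids(self) -> list[str]:
        return [f"MID{i + 1}" for i in range(self.n_samples)]


@dataclass
class TruthSet:
    """Ground truth: planted variants, artifact sites, read bookkeeping."""

    planted: dict[VariantKey, set[str]] = field(default_factory=dict)
    germline: dict[VariantKey, bool] = field(default_factory=dict)
    systematic: dict[VariantKey, set[str]] = field(default_factory=dict)
    read_counts: dict[str, int] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def validate(self) -> None:
        shared = set(self.planted) & set(self.systematic)
        if shared:
            raise ValueError(f"planted and systematic keys overlap: {shared}")


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, n)])


def _make_gene(rng: np.random.Generator, gene_id: str, chrom: str,
               slot_start: int, slot_end: int) -> GeneModel:
    """One random gene inside a slot, CDS length divisible by 3.

    The transcript is placed leaving >= 1700 bases of upstream margin in
    the slot so promoter windows and padded regions stay on-chromosome
    and read windows never clip.
    """
    n_exons = int(rng.integers(2, 6))
    exon_lens = rng.integers(120, 500, n_exons)
    intron_lens = rng.integers(200, 800, n_exons - 1) if n_exons > 1 else []
    tx_start = slot_start + 1700 + int(rng.integers(0, 200))
    exons, pos = [], tx_start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    tx_end = exons[-1][1]
    if tx_end > slot_end:
        raise ValueError(f"{gene_id}: slot too small for gene span")
    strand = "+" if rng.random() < 0.5 else "-"
    spliced = int(exon_lens.sum())
    utr5 = int(rng.integers(30, 121))
    utr3 = int(rng.integers(30, 151))
    if spliced - utr5 - utr3 < 92:  # keep CDS >= 90 after frame trim
        utr5 = utr3 = 30
    cds_len = spliced - utr5 - utr3
    cds_len -= cds_len % 3
    if cds_len < 90:
        raise ValueError(f"{gene_id}: CDS too short")

    # map spliced translation-order indices to genomic offsets
    def genomic(i: int) -> int:
        if strand == "-":
            i = spliced - 1 - i
        for s, e in exons:
            if i < e - s:
                return s + i
            i -= e - s
        raise AssertionError

    g_first = genomic(utr5)
    g_last = genomic(utr5 + cds_len - 1)
    cds_start, cds_end = min(g_first, g_last), max(g_first, g_last) + 1
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     tx_start=tx_start, tx_end=tx_end, exons=exons,
                     cds_start=cds_start, cds_end=cds_end)


def simulate_genome_and_genes(config: SimulationConfig,
                              rng: np.random.Generator | None = None
                              ) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Random genome plus valid gene models, deterministic for a seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    per_chrom = -(-config.n_genes // config.n_chroms)  # ceil
    slot = config.chrom_length // per_chrom
    if slot < 8000:
        raise ValueError("n_genes too large for chrom_length "
                         "(need >= 8 kb per gene slot)")
    genome = ReferenceGenome()
    genes: list[GeneModel] = []
    gid = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        genome[chrom] = _random_sequence(rng, config.chrom_length)
        for si in range(per_chrom):
            if gid >= config.n_genes:
                break
            genes.append(_make_gene(rng, f"GENE{gid + 1:03d}", chrom,
                                    si * slot, min((si + 1) * slot,
                                                   config.chrom_length)))
            gid += 1
    return genome, genes


def gene_manifest(genes: Sequence[GeneModel]) -> dict:
    """Generator manifest: per-gene exon counts and exon base totals."""
    return {
        "exon_counts": {g.gene_id: len(g.exons) for g in genes},
        "exon_bases": {g.gene_id: sum(e - s for s, e in g.exons)
                       for g in genes},
    }


# ---------------------------------------------------------------------------
# Staining table
# ---------------------------------------------------------------------------

def simulate_staining_table(config: SimulationConfig,
                            gene_ids: Sequence[str],
                            rng: np.random.Generator,
                            ) -> tuple[list[StainingRecord], dict]:
    """HPA-style table in which the first ``n_hpa_genes`` genes qualify
    under the up-in-tumor criteria, the remaining genes are 'literature'
    additions, and decoy proteins fail the criteria."""
    records: list[StainingRecord] = []
    qualifying = list(gene_ids[:config.n_hpa_genes])
    literature = list(gene_ids[config.n_hpa_genes:])
    normal_patients = [f"N{i + 1}" for i in range(3)]
    tumor_patients = [f"T{i + 1}" for i in range(8)]

    def add(pid, tissue, patient, level):
        records.append(StainingRecord(
            protein_id=pid, tissue=tissue, patient_id=patient, level=level,
            validation_score=int(rng.integers(1, 4)),
            transmembrane=bool(rng.random() < 0.3),
            signal_peptide=bool(rng.random() < 0.2)))

    for pid in qualifying:
        for p in normal_patients:
            add(pid, "normal_glandular", p, "none")
        n_strong = int(rng.integers(5, 9))
        lv = (["strong"] * n_strong
              + [str(rng.choice(["weak", "moderate"]))
                 for _ in range(8 - n_strong)])
        rng.shuffle(lv)
        for p, level in zip(tumor_patients, lv):
            add(pid, "tumor", p, level)
    for i in range(config.n_decoy_proteins):
        pid = f"DECOY{i + 1:02d}"
        # fail either the normal-tissue or the tumor-count requirement
        if rng.random() < 0.5:
            levels_normal = ["none", "weak", "none"]
            n_strong = int(rng.integers(5, 9))
        else:
            levels_normal = ["none"] * 3
            n_strong = int(rng.integers(0, 5))
        for p, level in zip(normal_patients, levels_normal):
            add(pid, "normal_glandular", p, level)
        lv = (["strong"] * n_strong
              + ["weak"] * (8 - n_strong))
        for p, level in zip(tumor_patients, lv):
            add(pid, "tumor", p, level)
    manifest = {"hpa_selected": sorted(qualifying), "literature": literature}
    return records, manifest


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------

def _target_position_pools(genome: ReferenceGenome,
                           genes: Sequence[GeneModel],
                           design: TargetDesign
                           ) -> tuple[list[tuple[str, int]],
                                      list[tuple[str, int]]]:
    """Coding and non-coding position pools inside the target."""
    masks = design.chrom_masks(genome.lengths())
    cds_masks = {c: np.zeros(n, dtype=bool) for c, n in genome.lengths().items()}
    for g in genes:
        for s, e in g.cds_segments():
            cds_masks[g.chrom][s:e] = True
    coding, noncoding = [], []
    for chrom in sorted(masks):
        tgt = masks[chrom]
        for p in np.flatnonzero(tgt & cds_masks[chrom]):
            coding.append((chrom, int(p)))
        for p in np.flatnonzero(tgt & ~cds_masks[chrom]):
            noncoding.append((chrom, int(p)))
    return coding, noncoding


def plant_variants(config: SimulationConfig, genome: ReferenceGenome,
                   genes: Sequence[GeneModel], design: TargetDesign,
                   rng: np.random.Generator) -> TruthSet:
    """Plant per-sample heterozygous germline variants.

    Each sample draws a binomial number of positions at the configured
    density per compartment; the alternative allele at a position is
    fixed per position, so samples hitting the same position share the
    same variant key.  A configured fraction of variants is additionally
    copied into other samples (recurrence).
    """
    if not design.regions:
        raise ValueError("empty target design")
    coding_pool, noncoding_pool = _target_position_pools(genome, genes, design)
    truth = TruthSet()
    alt_at: dict[tuple[str, int], str] = {}

    def alt_for(chrom: str, pos: int) -> str:
        site = (chrom, pos)
        if site not in alt_at:
            ref = genome[chrom][pos]
            choices = [b for b in BASES if b != ref]
            alt_at[site] = choices[int(rng.integers(0, 3))]
        return alt_at[site]

    events = []
    for sample in config.sample_ids:
        for pool, density in ((coding_pool, config.coding_het_density),
                              (noncoding_pool, config.noncoding_het_density)):
            if not pool or density == 0:
                continue
            n = int(rng.binomial(len(pool), density))
            idx = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
            for i in idx:
                chrom, pos = pool[int(i)]
                if genome[chrom][pos] == "N":
                    continue
                events.append((sample, chrom, pos))
    for sample, chrom, pos in events:
        key = (chrom, pos, genome[chrom][pos], alt_for(chrom, pos))
        truth.planted.setdefault(key, set()).add(sample)
        truth.germline[key] = True
    # recurrence: copy a fraction of variants into extra samples
    if config.recurrence_prob > 0 and config.n_samples > 1:
        for key in sorted(truth.planted):
            if rng.random() < config.recurrence_prob:
                carriers = truth.planted[key]
                others = [s for s in config.sample_ids if s not in carriers]
                if others:
                    extra = rng.choice(len(others),
                                       size=min(int(rng.integers(1, 3)),
                                                len(others)),
                                       replace=False)
                    for i in extra:
                        carriers.add(others[int(i)])
    truth.manifest["n_planted_coding"] = sum(
        1 for (c, p, _, _) in truth.planted
        if any(s <= p < e for g in genes if g.chrom == c
               for s, e in g.cds_segments()))
    truth.manifest["coding_pool_size"] = len(coding_pool)
    truth.manifest["noncoding_pool_size"] = len(noncoding_pool)
    return truth


def add_systematic_sites(config: SimulationConfig, genome: ReferenceGenome,
                         genes: Sequence[GeneModel], design: TargetDesign,
                         truth: TruthSet, rng: np.random.Generator) -> None:
    """Pick artifact sites that will masquerade as novel non-synonymous
    candidates: coding positions, absent from the planted set, with an
    alternative allele that changes the amino acid."""
    coding_pool, _ = _target_position_pools(genome, genes, design)
    planted_pos = {(c, p) for (c, p, _, _) in truth.planted}
    # affected samples drawn among adequately covered libraries
    eligible = [s for s, cov in zip(config.sample_ids, config.mean_coverage)
                if cov >= 15]
    placed, attempts = 0, 0
    while placed < config.n_systematic_sites and attempts < 2000:
        attempts += 1
        chrom, pos = coding_pool[int(rng.integers(0, len(coding_pool)))]
        if (chrom, pos) in planted_pos:
            continue
        ref = genome[chrom][pos]
        alts = [b for b in BASES if b != ref]
        rng.shuffle(alts)
        chosen = None
        for alt in alts:
            probe = SnvCall(sample_id="_", chrom=chrom, pos=pos,
                            ref_base=ref, alt_base=alt, depth=1, alt_count=1)
            ann = annotate_variant(probe, genes, genome, config.promoter_len)
            if ann.effect == "non_synonymous":
                chosen = alt
                break
        if chosen is None:
            continue
        key = (chrom, pos, ref, chosen)
        if key in truth.systematic:
            continue
        sample = eligible[int(rng.integers(0, len(eligible)))]
        truth.systematic[key] = {sample}
        planted_pos.add((chrom, pos))
        placed += 1
    if placed < config.n_systematic_sites:
        raise ValueError("could not place all systematic-error sites")
    truth.validate()


def make_catalog(config: SimulationConfig, genome: ReferenceGenome,
                 design: TargetDesign, truth: TruthSet,
                 rng: np.random.Generator) -> set[VariantKey]:
    """Known-variant catalog: a configured fraction of the planted
    variants plus catalog-only entries at positions never varied.
    Systematic-error sites are never in the catalog (they must surface
    as novel)."""
    catalog: set[VariantKey] = set()
    known_flags = {}
    for key in sorted(truth.planted):
        known = rng.random() < config.catalog_fraction
        known_flags[key] = known
        if known:
            catalog.add(key)
    taken = ({(c, p) for (c, p, _, _) in truth.planted}
             | {(c, p) for (c, p, _, _) in truth.systematic})
    positions = [(r.chrom, p) for r in design.regions
                 for p in range(r.start, r.end)]
    added = 0
    while added < config.n_catalog_extra and positions:
        chrom, pos = positions[int(rng.integers(0, len(positions)))]
        if (chrom, pos) in taken:
            continue
        ref = genome[chrom][pos]
        alt = [b for b in BASES if b != ref][int(rng.integers(0, 3))]
        if (chrom, pos, ref, alt) in catalog:
            continue
        catalog.add((chrom, pos, ref, alt))
        added += 1
    truth.manifest["catalog_known_flags"] = known_flags
    return catalog


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _read_clusters(design: TargetDesign, read_length: int
                   ) -> list[GenomicInterval]:
    """Merge target regions closer than one read length so uniform read
    starts over each cluster window give uniform expected depth at every
    target position."""
    clusters: list[GenomicInterval] = []
    for r in sorted(design.regions, key=lambda r: (r.chrom, r.start)):
        if clusters and clusters[-1].chrom == r.chrom and \
                r.start - clusters[-1].end < read_length:
            last = clusters[-1]
            clusters[-1] = GenomicInterval(last.chrom, last.start,
                                           max(last.end, r.end))
        else:
            clusters.append(GenomicInterval(r.chrom, r.start, r.end))
    return clusters


def simulate_reads(config: SimulationConfig, genome: ReferenceGenome,
                   design: TargetDesign, truth: TruthSet,
                   rng: np.random.Generator
                   ) -> tuple[list[BarcodedRead], dict]:
    """Barcoded reads with planted alleles, artifact alleles and uniform
    substitution errors; also off-target reads that never touch the
    target.  Expected depth at every target position equals the sample's
    configured mean coverage."""
    L = config.read_length
    clusters = _read_clusters(design, L)
    for c in clusters:
        if c.start - L + 1 < 0 or c.end + L - 1 > genome.length(c.chrom):
            raise ValueError(f"cluster {c} too close to chromosome bound "
                             f"for read length {L}")
    # per-sample variant tables: position -> (alt, emission fraction)
    var_tables: dict[str, dict[str, tuple[np.ndarray, list]]] = {}
    for sample in config.sample_ids:
        per_chrom: dict[str, list] = {}
        for source, frac in ((truth.planted, 0.5),
                             (truth.systematic,
                              config.systematic_alt_fraction)):
            for (chrom, pos, ref, alt), carriers in source.items():
                if sample in carriers:
                    per_chrom.setdefault(chrom, []).append((pos, alt, frac))
        var_tables[sample] = {}
        for chrom, entries in per_chrom.items():
            entries.sort()
            var_tables[sample][chrom] = (
                np.array([e[0] for e in entries]), entries)

    # off-target start pool: positions where a read cannot touch the target
    masks = design.chrom_masks(genome.lengths())
    off_pool: list[tuple[str, np.ndarray]] = []
    for chrom in sorted(masks):
        cs = np.concatenate([[0], np.cumsum(masks[chrom])])
        max_start = genome.length(chrom) - L
        starts = np.arange(max_start + 1)
        overlap = cs[starts + L] - cs[starts]
        off_pool.append((chrom, starts[overlap == 0]))
    off_weights = np.array([len(p) for _, p in off_pool], dtype=float)
    off_weights /= off_weights.sum()

    reads: list[BarcodedRead] = []
    manifest_counts: dict[str, dict[str, int]] = {}
    rid = 0
    base_order = {b: i for i, b in enumerate(BASES)}

    def mutate(sample: str, chrom: str, start: int) -> str:
        seq = genome[chrom][start:start + L]
        muts: dict[int, str] = {}
        table = var_tables[sample].get(chrom)
        if table is not None:
            pos_arr, entries = table
            i0, i1 = np.searchsorted(pos_arr, (start, start + L))
            for i in range(i0, i1):
                pos, alt, frac = entries[i]
                if rng.random() < frac:
                    muts[pos - start] = alt
        n_err = int(rng.poisson(L * config.error_rate))
        for _ in range(n_err):
            off = int(rng.integers(0, L))
            cur = muts.get(off, seq[off])
            muts[off] = BASES[(base_order[cur] + int(rng.integers(1, 4))) % 4]
        if not muts:
            return seq
        out = list(seq)
        for off, b in muts.items():
            out[off] = b
        return "".join(out)

    for sample, cov in zip(config.sample_ids, config.mean_coverage):
        n_on = n_off_total = 0
        for c in clusters:
            window = len(c) + L - 1
            n = int(rng.poisson(cov * window / L)) if cov > 0 else 0
            if n == 0:
                continue
            starts = rng.integers(c.start - L + 1, c.end, n)
            for s in starts:
                reads.append(BarcodedRead(f"r{rid:07d}", sample, c.chrom,
                                          int(s), mutate(sample, c.chrom,
                                                         int(s))))
                rid += 1
            n_on += n
        if config.off_target_fraction > 0 and n_on > 0:
            frac = config.off_target_fraction
            n_off = int(round(n_on * frac / (1 - frac)))
            chrom_idx = rng.choice(len(off_pool), size=n_off, p=off_weights)
            for ci in chrom_idx:
                chrom, pool = off_pool[int(ci)]
                s = int(pool[int(rng.integers(0, len(pool)))])
                seq = genome[chrom][s:s + L]
                reads.append(BarcodedRead(f"r{rid:07d}", sample, chrom, s, seq))
                rid += 1
                n_off_total += 1
        manifest_counts[sample] = {"on_target": n_on, "off_target": n_off_total,
                                   "total": n_on + n_off_total}
        truth.read_counts[sample] = n_on + n_off_total
    manifest = {"read_counts": manifest_counts,
                "n_reads_total": len(reads)}
    truth.manifest["read_manifest"] = manifest
    return reads, manifest


# ---------------------------------------------------------------------------
# Verification oracle
# ---------------------------------------------------------------------------

def sanger_oracle(truth: TruthSet) -> Callable[[VariantKey], str]:
    """Orthogonal-verification stand-in: a planted germline key verifies
    (it is present in tumor and matched normal tissue); any other
    candidate is a false positive."""

    def verify(key: VariantKey) -> str:
        if key in truth.planted and truth.germline.get(key, False):
            return "verified"
        return "false_positive"

    return verify
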