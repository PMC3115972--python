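"""Demultiplexing, pileup, SNV calling, annotation, novelty, recurrence,
verification."""

from collections import Counter, defaultdict

import numpy as np
import pytest

from snvfunnel.gene_models import ReferenceGenome, RegionClass
from snvfunnel.target_design import summarize_design
from snvfunnel.gene_models import GenomicInterval
from snvfunnel.variant_pipeline import (
    BarcodedRead,
    SnvCall,
    annotate_variant,
    build_pileup,
    call_snvs,
    compute_recurrence,
    demultiplex,
    flag_novelty,
    read_reads_tsv,
    translate_cds_with_variant,
    unique_variants,
    verify_candidates,
    write_reads_tsv,
    write_vcf,
)

from conftest import make_gene


def read(rid, mid, start, seq, chrom="chr1"):
    return BarcodedRead(rid, mid, chrom, start, seq)


def design_over(genome, spans):
    regions = [GenomicInterval(c, s, e) for c, s, e in spans]
    return summarize_design(regions, [])


class TestDemultiplex:
    def test_counts_by_tag(self):
        reads = [read(f"r{i}", "MID1", 0, "ACGT") for i in range(3)]
        reads += [read(f"s{i}", "MID2", 0, "ACGT") for i in range(2)]
        bins = demultiplex(reads, ["MID1", "MID2"])
        assert {k: len(v) for k, v in bins.items()} == \
            {"MID1": 3, "MID2": 2, "unassigned": 0}

    def test_unknown_tag_goes_unassigned(self):
        bins = demultiplex([read("r0", "MID9", 0, "ACGT")], ["MID1"])
        assert len(bins["unassigned"]) == 1

    def test_duplicate_barcode_is_config_error(self):
        with pytest.raises(ValueError):
            demultiplex([], ["MID1", "MID1"])

    def test_conservation_and_manifest_counts(self, study):
        bins = demultiplex(study.reads, study.config.sample_ids)
        total = sum(len(v) for v in bins.values())
        assert total == len(study.reads)
        assert len(bins["unassigned"]) == 0
        for sample in study.config.sample_ids:
            assert len(bins[sample]) == study.truth.read_counts[sample]


class TestBuildPileup:
    def test_single_read_depths(self, flat_genome):
        design = design_over(flat_genome, [("chr1", 0, 100)])
        pileup = build_pileup({"S": [read("r0", "S", 10, "AAAAA")]},
                              flat_genome, design)
        for pos in range(10, 15):
            assert pileup.depth("S", "chr1", pos) == 1
        assert pileup.depth("S", "chr1", 9) == 0
        assert pileup.depth("S", "chr1", 15) == 0

    def test_positions_outside_target_dropped(self, flat_genome):
        design = design_over(flat_genome, [("chr1", 12, 14)])
        pileup = build_pileup({"S": [read("r0", "S", 10, "AAAAA")]},
                              flat_genome, design)
        assert pileup.depth("S", "chr1", 10) == 0
        assert pileup.depth("S", "chr1", 12) == 1
        assert pileup.bases_on_target["S"] == 2

    def test_zero_reads_empty_pileup(self, flat_genome):
        design = design_over(flat_genome, [("chr1", 0, 100)])
        pileup = build_pileup({"S": []}, flat_genome, design)
        assert pileup.counts["S"]["chr1"].sum() == 0

    def test_read_past_chromosome_end_truncated(self, flat_genome, caplog):
        design = design_over(flat_genome, [("chr1", 9990, 10000)])
        with caplog.at_level("WARNING", logger="snvfunnel"):
            pileup = build_pileup(
                {"S": [read("r0", "S", 9995, "ACGTACGTAC")]},
                flat_genome, design)
        assert pileup.depth("S", "chr1", 9999) == 1
        assert any("truncated" in m for m in caplog.messages)

    def test_brute_force_tally_oracle(self, rng, flat_genome):
        """Pileup of 2,000 random reads equals an independent per-base
        dictionary tally."""
        design = design_over(flat_genome, [("chr1", 1000, 3000)])
        reads = []
        for i in range(2000):
            start = int(rng.integers(900, 3050))
            length = int(rng.integers(5, 60))
            seq = "".join(np.array(list("ACGTN"))[
                rng.integers(0, 5, length)])
            reads.append(read(f"r{i}", "S", start, seq))
        pileup = build_pileup({"S": reads}, flat_genome, design)
        tally = defaultdict(Counter)
        for r in reads:
            for off, b in enumerate(r.sequence):
                pos = r.start + off
                if 1000 <= pos < 3000 and pos < 10000 and b != "N":
                    tally[pos][b] += 1
        for pos in range(1000, 3000):
            assert pileup.base_counts("S", "chr1", pos) == \
                {b: tally[pos].get(b, 0) for b in "ACGT"}


class TestCallSnvs:
    def make_pileup(self, genome, counts_by_pos):
        """Pileup with explicit per-position base counts for sample S."""
        design = design_over(genome, [("chr1", 0, 100)])
        from snvfunnel.variant_pipeline import Pileup, BASE_INDEX
        pileup = Pileup(["S"], genome.lengths(),
                        design.chrom_masks(genome.lengths()))
        for pos, counts in counts_by_pos.items():
            for b, n in counts.items():
                pileup.counts["S"]["chr1"][BASE_INDEX[b], pos] = n
        return pileup

    def test_exact_threshold_fraction_not_called(self, flat_genome):
        # position 0 has reference A; 2/10 = 0.20 is NOT above the threshold
        pileup = self.make_pileup(flat_genome, {0: {"A": 8, "C": 2}})
        assert call_snvs(pileup, flat_genome) == []

    def test_above_threshold_called(self, flat_genome):
        pileup = self.make_pileup(flat_genome, {0: {"A": 7, "C": 3}})
        (call,) = call_snvs(pileup, flat_genome)
        assert (call.ref_base, call.alt_base, call.depth) == ("A", "C", 10)
        assert call.alt_fraction == pytest.approx(0.3)

    def test_min_depth_enforced(self, flat_genome):
        pileup = self.make_pileup(flat_genome, {0: {"A": 2, "C": 2}})
        assert call_snvs(pileup, flat_genome) == []
        assert len(call_snvs(pileup, flat_genome, min_depth=4)) == 1

    def test_multiallelic_position_emits_both(self, flat_genome):
        pileup = self.make_pileup(flat_genome, {0: {"A": 4, "C": 3, "G": 3}})
        calls = call_snvs(pileup, flat_genome)
        assert {c.alt_base for c in calls} == {"C", "G"}

    def test_n_reference_position_skipped(self):
        genome = ReferenceGenome()
        genome["chr1"] = "N" + "ACGT" * 25
        pileup = self.make_pileup(genome, {0: {"A": 10}})
        assert call_snvs(pileup, genome) == []

    def test_brute_force_scan_oracle(self, study):
        """The call set over the full synthetic pileup equals a position-by-
        position brute-force application of the calling rule."""
        expected = set()
        genome, pileup = study.genome, study.pileup
        for sample in pileup.sample_ids:
            for chrom, counts in pileup.counts[sample].items():
                for r in study.design.regions:
                    if r.chrom != chrom:
                        continue
                    for pos in range(r.start, r.end):
                        col = counts[:, pos]
                        depth = int(col.sum())
                        if depth < 5:
                            continue
                        ref = genome[chrom][pos]
                        for bi, b in enumerate("ACGT"):
                            if b != ref and col[bi] / depth > 0.20:
                                expected.add((sample, chrom, pos, ref, b))
        got = {(c.sample_id, c.chrom, c.pos, c.ref_base, c.alt_base)
               for c in study.calls}
        assert got == expected

    def test_monotonicity_in_thresholds(self, study):
        base = {(c.sample_id, c.key) for c in study.calls}
        stricter_frac = {(c.sample_id, c.key) for c in call_snvs(
            study.pileup, study.genome, min_fraction=0.35)}
        stricter_depth = {(c.sample_id, c.key) for c in call_snvs(
            study.pileup, study.genome, min_depth=15)}
        assert stricter_frac <= base
        assert stricter_depth <= base

    def test_call_counts_rederivable_from_pileup(self, study):
        for c in study.calls[:200]:
            counts = study.pileup.base_counts(c.sample_id, c.chrom, c.pos)
            assert sum(counts.values()) == c.depth
            assert counts[c.alt_base] == c.alt_count


class TestAnnotateVariant:
    def genome_with(self, codon_seq, at, length=8000):
        genome = ReferenceGenome()
        seq = list("A" * length)
        seq[at:at + len(codon_seq)] = list(codon_seq)
        genome["chr1"] = "".join(seq)
        return genome

    def call_at(self, pos, ref, alt, sample="S"):
        return SnvCall(sample_id=sample, chrom="chr1", pos=pos, ref_base=ref,
                       alt_base=alt, depth=10, alt_count=5)

    def test_intronic_call_non_coding(self):
        gene = make_gene(exons=[(2000, 2400), (2600, 3200)])
        genome = self.genome_with("", 0)
        ann = annotate_variant(self.call_at(2500, "A", "G"), [gene], genome)
        assert ann.region_class is RegionClass.INTRON
        assert ann.effect == "non_coding" and ann.aa_change is None

    def test_missense_third_base(self):
        # codon ATG at CDS start; third base G->A gives ATA: M -> I
        gene = make_gene(exons=[(2000, 3200)], cds_start=2300, cds_end=3002)
        genome = self.genome_with("ATG", 2300)
        ann = annotate_variant(self.call_at(2302, "G", "A"), [gene], genome)
        assert ann.effect == "non_synonymous"
        assert ann.aa_change == ("M", 0, "I")

    def test_silent_third_base(self):
        # codon CTG, third base G->A gives CTA: L -> L
        gene = make_gene(exons=[(2000, 3200)], cds_start=2300, cds_end=3002)
        genome = self.genome_with("CTG", 2300)
        ann = annotate_variant(self.call_at(2302, "G", "A"), [gene], genome)
        assert ann.effect == "synonymous"
        assert ann.aa_change == ("L", 0, "L")

    def test_minus_strand_codon_rebuilt(self):
        # minus-strand CDS [2300,3000); genomic CAT at 2997..3000 reads as
        # ATG in translation orientation; G->A at genomic 2997 (C->T there)
        gene = make_gene(strand="-", exons=[(2000, 3200)],
                         cds_start=2298, cds_end=3000)
        genome = self.genome_with("CAT", 2997)
        ann = annotate_variant(self.call_at(2997, "C", "T"), [gene], genome)
        assert ann.aa_change[0] == "M"
        assert ann.effect == "non_synonymous"

    def test_broken_frame_flagged_unannotatable(self, caplog):
        gene = make_gene(exons=[(2000, 3200)], cds_start=2300, cds_end=3001)
        genome = self.genome_with("ATG", 2300)
        with caplog.at_level("WARNING", logger="snvfunnel"):
            ann = annotate_variant(self.call_at(2302, "G", "A"), [gene],
                                   genome)
        assert not ann.annotatable and ann.effect == "non_coding"

    def test_full_protein_oracle_on_study(self, study):
        """Single-codon effect shortcut agrees with translating the entire
        mutated CDS, for every CDS variant of the synthetic study."""
        from Bio.Seq import Seq
        from snvfunnel.gene_models import spliced_cds_sequence
        genes = {g.gene_id: g for g in study.genes}
        checked = 0
        for v in study.variants:
            if v.region_class is not RegionClass.CDS or not v.annotatable:
                continue
            gene = genes[v.gene_id]
            ref_protein = str(Seq(
                spliced_cds_sequence(gene, study.genome)).translate())
            alt_protein = translate_cds_with_variant(
                gene, study.genome, v.pos, v.alt)
            assert (v.effect == "synonymous") == (ref_protein == alt_protein)
            checked += 1
        assert checked > 30

    def test_annotation_order_independent(self, study):
        reordered = list(reversed(study.calls))
        variants = unique_variants(reordered, study.genes, study.genome,
                                   study.config.promoter_len)
        assert {v.key: (v.region_class, v.effect) for v in variants} == \
            {v.key: (v.region_class, v.effect) for v in study.variants}


class TestNoveltyRecurrenceVerification:
    def ann(self, pos, novel=None, chrom="chr1", ref="A", alt="G"):
        from snvfunnel.variant_pipeline import AnnotatedVariant
        return AnnotatedVariant(chrom, pos, ref, alt,
                                region_class=RegionClass.INTRON,
                                effect="non_coding", novel=novel)

    def test_catalog_member_not_novel(self, flat_genome):
        variants = flag_novelty([self.ann(100, ref="A", alt="G")],
                                {("chr1", 100, "A", "G")}, flat_genome)
        assert variants[0].novel is False

    def test_empty_catalog_all_novel(self, flat_genome):
        variants = flag_novelty([self.ann(100)], set(), flat_genome)
        assert variants[0].novel is True

    def test_position_mode_matches_any_allele(self, flat_genome):
        variants = flag_novelty([self.ann(100, ref="A", alt="G")],
                                {("chr1", 100, "A", "T")}, flat_genome,
                                match_mode="position")
        assert variants[0].novel is False

    def test_catalog_ref_mismatch_warns_and_keeps(self, flat_genome, caplog):
        with caplog.at_level("WARNING", logger="snvfunnel"):
            variants = flag_novelty([self.ann(100, ref="A", alt="G")],
                                    {("chr1", 100, "T", "G")}, flat_genome,
                                    match_mode="position")
        assert any("mismatch" in m for m in caplog.messages)
        assert variants[0].novel is False  # entry kept despite the mismatch

    def test_novelty_complement_matches_manifest(self, study):
        known_flags = study.truth.manifest["catalog_known_flags"]
        for v in study.variants:
            if v.key in known_flags:
                assert v.novel == (not known_flags[v.key])

    def test_recurrence_counting(self):
        calls = [
            SnvCall("MID1", "chr1", 5, "A", "G", 10, 5),
            SnvCall("MID4", "chr1", 5, "A", "G", 12, 6),
            SnvCall("MID1", "chr1", 5, "A", "G", 10, 5),  # same sample twice
            SnvCall("MID2", "chr2", 9, "C", "T", 10, 4),
        ]
        rec = compute_recurrence(calls)
        assert rec[("chr1", 5, "A", "G")] == 2
        assert rec[("chr2", 9, "C", "T")] == 1

    def test_recurrence_brute_force_group_by(self, study):
        expected = defaultdict(set)
        for c in study.calls:
            expected[c.key].add(c.sample_id)
        assert compute_recurrence(study.calls) == \
            {k: len(v) for k, v in expected.items()}

    def test_verification_split(self):
        planted = self.ann(100)
        artifact = self.ann(200)
        oracle = lambda key: ("verified" if key[1] == 100
                              else "false_positive")
        verified = verify_candidates([planted, artifact], oracle)
        assert [v.verification for v in verified] == \
            ["verified", "false_positive"]

    def test_oracle_must_be_total(self):
        oracle = lambda key: None
        with pytest.raises(ValueError):
            verify_candidates([self.ann(100)], oracle)

    def test_planted_sensitivity_at_depth(self, study):
        """Planted heterozygous variants at pileup depth >= 20 are called
        with sensitivity >= 0.99 (binomial tail: at p=0.5 and depth >= 20,
        the chance of an alt fraction <= 0.20 is < 0.6%)."""
        from snvfunnel.workflow import sensitivity
        sens, n = sensitivity(study, min_true_depth=20)
        assert n > 100
        assert sens >= 0.99


class TestReadAndVcfIO:
    def test_reads_tsv_round_trip(self, tmp_path, study):
        path = tmp_path / "reads.tsv"
        subset = study.reads[:50]
        write_reads_tsv(path, subset)
        assert read_reads_tsv(path) == subset

    def test_vcf_round_trip_with_cyvcf2(self, tmp_path, study):
        """VCF written via pysam re-reads with an independent parser; spot
        checks 1-based conversion and per-sample depth."""
        from cyvcf2 import VCF
        path = tmp_path / "calls.vcf"
        write_vcf(path, study.calls, study.genome, study.config.sample_ids)
        seen = {}
        for rec in VCF(str(path)):
            seen[(rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0])] = rec
        assert set(seen) == {c.key for c in study.calls}
        call = study.calls[0]
        rec = seen[call.key]
        sidx = study.config.sample_ids.index(call.sample_id)
        assert rec.format("DP")[sidx][0] == call.depth
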