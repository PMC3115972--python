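"""End-to-end synthetic study: simulate, design, call, annotate, verify,
report.

This is the glue that runs every stage in method order against the
synthetic generator's truth oracle; each stage is the corresponding
library function, so the workflow adds bookkeeping only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import hpa_selection, reporting, synthetic_data, target_design
from . import variant_pipeline as vp
from .gene_models import GeneModel, ReferenceGenome
from .hpa_selection import UP_IN_TUMOR
from .reporting import CoverageRow, FunnelCounts
from .synthetic_data import SimulationConfig, TruthSet
from .target_design import TargetDesign

logger = logging.getLogger("snvfunnel")


@dataclass
class StudyResult:
    """Everything a synthetic end-to-end run produces."""

    config: SimulationConfig
    genome: ReferenceGenome
    genes: list[GeneModel]
    staining: list
    selected_proteins: list[str]
    design: TargetDesign
    truth: TruthSet
    catalog: set
    reads: list
    reads_by_sample: dict
    pileup: vp.Pileup
    calls: list[vp.SnvCall]
    variants: list[vp.AnnotatedVariant]   # unique, annotated, novelty+recurrence set
    candidates: list[vp.AnnotatedVariant]  # novel non-synonymous, verified
    oracle: Callable
    coverage_rows: list[CoverageRow]
    coverage_total: CoverageRow
    rates: tuple[float, float]
    funnel: FunnelCounts
    fp_rate: float | None


def run_synthetic_study(config: SimulationConfig | None = None) -> StudyResult:
    """Run the full pipeline on a freshly simulated study."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    # 1. genome, gene models, staining table, protein selection
    genome, genes = synthetic_data.simulate_genome_and_genes(config, rng)
    staining, stain_manifest = synthetic_data.simulate_staining_table(
        config, [g.gene_id for g in genes], rng)
    hpa_selected = hpa_selection.select_candidates(staining, UP_IN_TUMOR)
    selected = hpa_selection.merge_with_literature(
        hpa_selected, stain_manifest["literature"])
    selected_genes = [g for g in genes if g.gene_id in set(selected)]

    # 2. capture target design
    design = target_design.design_targets(
        selected_genes, genome.lengths(),
        promoter_len=config.promoter_len, min_len=config.min_region_len)

    # 3. truth: planted germline variants, artifact sites, catalog, reads
    truth = synthetic_data.plant_variants(config, genome, selected_genes,
                                          design, rng)
    synthetic_data.add_systematic_sites(config, genome, selected_genes,
                                        design, truth, rng)
    catalog = synthetic_data.make_catalog(config, genome, design, truth, rng)
    reads, _ = synthetic_data.simulate_reads(config, genome, design, truth, rng)
    truth.manifest["stain_manifest"] = stain_manifest

    # 4. demultiplex, pileup, call
    bins = vp.demultiplex(reads, config.sample_ids)
    reads_by_sample = {s: bins[s] for s in config.sample_ids}
    pileup = vp.build_pileup(reads_by_sample, genome, design)
    calls = vp.call_snvs(pileup, genome)

    # 5. annotate, novelty, recurrence
    variants = vp.unique_variants(calls, selected_genes, genome,
                                  config.promoter_len)
    variants = vp.flag_novelty(variants, catalog, genome)
    variants = vp.apply_recurrence(variants, vp.compute_recurrence(calls))

    # 6. verification of the candidate set (novel non-synonymous)
    oracle = synthetic_data.sanger_oracle(truth)
    candidates = [v for v in variants
                  if v.novel and v.effect == "non_synonymous"]
    candidates = vp.verify_candidates(candidates, oracle)
    verified_by_key = {v.key: v.verification for v in candidates}
    variants = [vp.replace_fields(v, verification=verified_by_key[v.key])
                if v.key in verified_by_key else v for v in variants]

    # 7. reports
    call_count = {s: 0 for s in config.sample_ids}
    coding_count = {s: 0 for s in config.sample_ids}
    coding_keys = {v.key for v in variants
                   if v.region_class.value == "CDS" and v.annotatable}
    for c in calls:
        call_count[c.sample_id] += 1
        if c.key in coding_keys:
            coding_count[c.sample_id] += 1
    tallies = [{
        "sample_id": s,
        "mapped_reads": pileup.reads_on_target[s],
        "mapped_bases": pileup.bases_on_target[s],
        "snv_count": call_count[s],
        "coding_snv_count": coding_count[s],
    } for s in config.sample_ids]
    rows, total = reporting.coverage_table(tallies, design.total_bases)
    rates = reporting.variation_rates(
        total.snv_count, total.coding_snv_count, config.n_samples,
        design.total_bases, design.coding_bases)
    funnel = reporting.build_funnel(variants)
    fp_rate = (reporting.false_positive_rate(
        funnel.novel_non_synonymous, funnel.verified_novel)
        if funnel.novel_non_synonymous else None)

    return StudyResult(
        config=config, genome=genome, genes=genes, staining=staining,
        selected_proteins=selected, design=design, truth=truth,
        catalog=catalog, reads=reads, reads_by_sample=reads_by_sample,
        pileup=pileup, calls=calls, variants=variants, candidates=candidates,
        oracle=oracle, coverage_rows=rows, coverage_total=total,
        rates=rates, funnel=funnel, fp_rate=fp_rate)


# -- truth-based metrics (used by tests and the acceptance script) ----------

def planted_events(result: StudyResult) -> list[tuple[str, tuple]]:
    """All (sample, key) pairs the generator planted."""
    return [(s, key) for key, carriers in result.truth.planted.items()
            for s in sorted(carriers)]


def sensitivity(result: StudyResult, min_true_depth: int = 0
                ) -> tuple[float, int]:
    """Fraction of planted (sample, key) events recovered by the caller,
    restricted to events whose pileup depth is >= ``min_true_depth``.
    Returns (sensitivity, number of eligible events)."""
    called = {(c.sample_id, c.key) for c in result.calls}
    eligible = hits = 0
    for sample, key in planted_events(result):
        chrom, pos, _, _ = key
        if result.pileup.depth(sample, chrom, pos) < min_true_depth:
            continue
        eligible += 1
        if (sample, key) in called:
            hits += 1
    return (hits / eligible if eligible else float("nan")), eligible


def called_planted_fractions(result: StudyResult,
                             min_coverage: int = 0) -> list[float]:
    """Alt fractions of called planted events, restricted to samples with
    configured mean coverage >= ``min_coverage``."""
    cov = dict(zip(result.config.sample_ids, result.config.mean_coverage))
    planted = set(result.truth.planted)
    return [c.alt_fraction for c in result.calls
            if c.key in planted and cov[c.sample_id] >= min_coverage]


def verification_agreement(result: StudyResult) -> bool:
    """True iff the pipeline's verified/false-positive partition of the
    candidate list equals the truth manifest's partition."""
    for v in result.candidates:
        truth_status = ("verified" if v.key in result.truth.planted
                        and result.truth.germline.get(v.key, False)
                        else "false_positive")
        if v.verification != truth_status:
            return False
    return True
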