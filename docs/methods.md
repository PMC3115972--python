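# Methods

## Pipeline model

The package models an up-front-filtered biomarker discovery study as six
deterministic stages over explicit data types.

**Coordinates.** All internal coordinates are 0-based half-open. BED
output stays 0-based half-open; VCF positions are converted to 1-based at
the writer, nowhere else. A gene model is single-transcript: transcript
bounds, sorted disjoint exons, and CDS bounds that must fall on exon
bases. The spliced CDS length must be divisible by three; the synthetic
generator enforces this, and real input violating it flags affected
variants as unannotatable rather than aborting (they are counted as
non-coding in the funnel).

**Region classification.** Each (gene, position) pair maps to exactly one
of PROMOTER, UTR5, CDS, INTRON, UTR3, INTERGENIC. The promoter is the
`promoter_len` (default 1,000 bp) window strand-upstream of the
transcript start — equivalently upstream of the 5′UTR, since the
transcript begins with its 5′UTR. UTR5/UTR3 are strand-aware. When
several genes claim a position, the pipeline-level class is resolved by
the precedence CDS > UTR5 > UTR3 > PROMOTER > INTRON > INTERGENIC,
favouring the most consequence-bearing class; ties inside one class break
on gene id for determinism.

**Staining selection.** Staining levels form the ordinal scale
none < weak < moderate < strong. The default up-in-tumor criteria require
*all* normal glandular records at `none` (an `any` mode is available —
the all/any choice is a genuine design freedom; *all* is the stricter and
default reading) and ≥ 5 distinct tumor patients at `strong`. The
down-in-tumor search mirrors this with ≥ 10 patients at
`none`/`weak`. Assay validation scores are carried through and can be
used as an optional minimum-score screen, but are not a hard filter by
default; transmembrane/signal-peptide flags are pass-through annotations
only.

**Target design.** Raw regions are the promoter window plus every exonic
segment, split at the CDS bounds so each interval is purely coding or
purely UTR; introns are excluded. Regions shorter than `min_len`
(default 250 bp) are padded symmetrically — the odd base goes to the
higher-coordinate side, and clamping at a chromosome bound pushes the
clamped share to the other side. Padding creates overlaps; strictly
overlapping regions are fused (bookended regions are kept separate, with
a `merge_adjacent` switch for users who prefer otherwise). Whether the
original expansion was symmetric or one-sided is not documented anywhere;
symmetric padding is the neutral choice. Coding bases of a design are the
target bases lying in any gene's CDS, which coincides with the precedence
rule because CDS ranks first. Region strand is dropped at design time:
hybridization capture is strand-agnostic.

**Calling.** Reads carry their true origin (the generator knows where
each read came from), so no aligner is involved and pileups are exact
per-base tallies restricted to the target. The caller emits (sample,
position, alt) whenever depth ≥ `min_depth` and alt/depth >
`min_fraction`, strictly. The published observation that all novel SNVs
sat above 20% of reads motivates the strict `> 0.20` default; the
`min_depth = 5` default is this package's own choice of a minimal
high-confidence criterion, since the original vendor caller's internal
definition is unpublished — the caller here is a documented substitute,
not a re-implementation of it. Multi-allelic positions yield one call per
alternative allele; "unique position" counts in the funnel count
positions, not alleles. N reference bases are skipped.

**Annotation and the funnel.** CDS calls rebuild the affected codon
strand-aware from the spliced CDS and translate it with the standard
nuclear code; a variant is synonymous iff the amino acid is unchanged (a
full-protein translation oracle in the tests confirms the single-codon
shortcut). Novelty defaults to exact (chrom, pos, ref, alt) matching
against the catalog, with a positional mode for catalog-era semantics.
Recurrence counts distinct samples per variant key. The funnel's position
rows count unique positions; its novelty rows count unique keys. Promoter
positions are "in target genes" but neither exonic nor intronic, so the
exon + intron rows sum to at most the in-gene row, with equality exactly
when no promoter-class positions occur.

**Verification.** The orthogonal verification step is modelled as a total
oracle over candidate keys: planted germline variants verify (they are
present in tumor and matched normal tissue), everything else is a false
positive. This reproduces the logic of confirming candidates by Sanger
sequencing both tissues without modelling chromatogram reading.

## Reporting conventions

Mean coverage is mapped bases / target bases rounded half away from zero
to an integer — the convention that reproduces every row of the published
per-sample table, including the 37.51 → 38 case. Variation rates are
per-sample averages: total calls divided by the number of samples, then
by the compartment's base count, as percent rounded half away from zero
to two decimals. This per-sample-average interpretation is adopted
because it is the only reading that reproduces the published 0.07% /
0.05% pair exactly from the published counts (1,494 non-coding calls /
10 samples / 214,083 non-coding bases = 0.0698%; 488 / 10 / 89,705 =
0.0544%).

## The synthetic study

`SimulationConfig` defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| genome | 3 chromosomes × 60 kb, 18 genes | desk-scale; ≥ 8 kb per gene slot keeps promoters, padding and read windows on-chromosome |
| samples | 10 libraries, coverage (33, 28, 3, 21, 28, 17, 18, 35, 7, 38)× | the published uneven profile: one near-dropout (~3×) and one underloaded (~7×) library |
| read length | 400 bp | long-read pyrosequencing regime |
| error rate | 0.1% per base | substitution-only, uniform |
| het densities | 0.05% coding, 0.07% non-coding per base per sample | match the observed per-base variation rates, so recovered ≈ planted at adequate coverage |
| recurrence | 5% of variants copied into 1–2 extra samples | produces a small shared-variant tail |
| catalog | 77% of planted variants known; 50 extra never-planted entries | the published novel fraction of non-synonymous variants (15/66 novel ≈ 77% known) |
| systematic errors | 6 sites, alt fraction 0.40, one adequately covered sample each | artifacts drawn to exceed the calling threshold with near-certainty, emulating the published six false positives |
| off-target reads | 77% of each library | echoes the ~22.6% on-target observation; off-target reads exercise demultiplexing and bookkeeping only and never overlap the target |

All randomness flows through a single `numpy.random.default_rng(seed)`
stream in a fixed stage order, so a configuration is fully deterministic.

Read starts are drawn uniformly over each region cluster's start window
(regions closer than one read length are clustered), sized so the
*expected depth at every target position equals the library's configured
coverage*; planted alleles are emitted per overlapping read with
probability 0.5 (heterozygous), systematic-error alleles with probability
0.40 in their affected sample.

What the generator does **not** emulate: alignment and mapping error
(reads carry known origin), homopolymer/flowgram error structure of
pyrosequencing, base qualities, indels and structural variants, somatic
vs germline mixtures (a somatic flag exists but defaults off — the
verified published candidates were all germline), capture thermodynamics
and GC bias. Passing tests therefore demonstrate the correctness of the
filter cascade and its statistical behaviour under an idealised error
model, not robustness to mapping or chemistry artifacts on real data.

## Numerical and degenerate-input choices

- Allele-fraction comparison uses floating division with a strict `>`;
  at the 0.20 boundary integer count patterns (2/10, 3/15) are excluded
  exactly.
- Rounding is half away from zero everywhere (`Decimal ROUND_HALF_UP` on
  the repr of the float), both for coverage integers and for 2-decimal
  rates.
- Empty region lists, zero-coverage libraries, zero densities, and empty
  variant sets all produce empty-but-valid outputs; zero target size and
  zero candidates are errors.
- Promoter windows falling entirely off-chromosome are dropped with a
  warning; partially off-chromosome windows are clamped.
- Reads extending past a chromosome end are truncated with a warning.
- Catalog entries whose reference base mismatches the genome warn and are
  kept.

## Test design

Brute-force oracles are independent re-implementations (per-base set
construction for classification and fusion, dictionary tallies for
pileups, position-by-position scans for calling, full-protein translation
for effects, group-by for recurrence) frozen in the test suite. The
statistical properties are asserted at the fixture seed with explicit
binomial bounds: planted-variant counts within 4σ of density × bases ×
samples, sensitivity ≥ 0.95 overall and ≥ 0.99 restricted to events at
pileup depth ≥ 20, and the heterozygous-band check ([0.25, 0.75])
asserted as a one-sided binomial tail bound on the out-of-band count at
rate 1%, restricted to libraries of configured coverage ≥ 20× — at ~25×
depth the exact in-band probability of a Binomial(depth, 0.5) fraction is
itself ≈ 0.99, so a raw ≥ 0.99 assertion on the empirical fraction would
reject a correctly behaving caller with non-trivial probability.

The default problem size (41.6 kb target, ~160 k reads, ~250 calls) keeps
one full end-to-end study at roughly fifteen seconds, which the test
suite shares as a session fixture.

## Known limitations

- Single-transcript gene models only; no isoform handling.
- The design stage does not model the manufacturer's repetitive-region
  filtering; an exclusion BED can be subtracted instead.
- Novelty flags depend entirely on the supplied catalog; the package does
  not model catalog errors (the published study itself found two of its
  six false positives later appearing in a newer catalog build).
- The verification oracle is perfectly accurate by construction; Sanger
  sensitivity limits (e.g. low-fraction somatic variants) are out of
  scope.
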