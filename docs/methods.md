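# Methods

`cftrscreen` re-implements, on a fully synthetic cohort, the analysis chain of a
clinical amplicon-sequencing screen of the CFTR gene: coverage quality control,
a thresholded variant filter cascade, pathogenicity tiering against reference
databases, depth-normalized multi-exon copy-number detection, poly-TG/poly-T
tract diplotyping, and diagnostic-accuracy statistics with 95% confidence
intervals. This note records the models behind each stage, the defaults and
why they hold, and what the synthetic data does and does not emulate.

## The synthetic cohort

**Gene and panel.** The reference is a toy ~14.5 kb gene with 27 exons
(21 × 390 bp, 6 × 300 bp, 150 bp introns), not a real genome build: every run
regenerates it from a seed, so no download or licensed resource is needed and
all coordinates are internal. Coding exons ± 15 bp of flank are tiled by 102
amplicons of exactly 150 bp in two primer pools. Tiling is computed per exon:
the minimal count that leaves ≥ 1 bp overlap between neighbours, then extra
amplicons are added to the sparsest exons until the panel reaches 102. Pools
alternate with global amplicon parity, which simultaneously guarantees that
overlapping neighbours never share a pool and that the pool-imbalance depth
mode (below) never aligns across two consecutive amplicons.

**The TG-T tract.** An intronic (TG)11(T)7 tract flanked by two fixed 10-bp
anchors is embedded upstream of exon 10, mimicking the c.1210−34 poly-TG-T
locus. The reference builder mutates any spurious anchor occurrence so each
anchor is unique. The amplicon tiling of exon 10 is extended so one insert
fully spans anchors + tract.

**Truth catalog.** ~23 variants patterned on the spectrum of a real screening
cohort of 177 patients: recurrent pathogenic SNVs and indels (including a
3 bp in-frame deletion carried hom/het by 13/10 per 177, the F508del pattern),
truncating and canonical-splice changes, missense variants resolved by
in-silico predictor votes, common neutral polymorphisms (up to 40% population
frequency), four "dropout-prone" loci that reproduce the coverage-loss
false-negative mechanism (designated carriers 2/30/1/4, mirroring the
reported four-variant FN breakdown), and one homozygous deletion of exons
4–11. Genotype frequencies are carrier counts per 177. Indels are placed so
that their left-aligned representation stays inside the target regions, clear
of amplicon-insert boundaries, and in the regional class (exonic/intronic)
their tier presumes; truth, caller and databases all share the same
left-aligned, parsimony-trimmed (pos, ref, alt) representation, so matching
is exact set arithmetic.

**Reads and depth.** Reads are placed gaplessly at their amplicon insert
(alignment is outside scope; indel alleles are encoded in the read sequence
and CIGAR). Per-amplicon read counts are negative binomial with mean

    mean_depth × insert_len / read_length / panel_redundancy × eff_a × pool_s

where `panel_redundancy` (~1.41) is the mean number of inserts covering a
target base — so `mean_depth = 852` produces an *observed* mean per-base
target depth of ~852X, the sense in which the platform prints it —
`eff_a` is a per-amplicon log-normal PCR efficiency (σ = 0.3) shared by every
sample, and `pool_s` is a per-sample log-normal relative yield of pool 1
versus pool 2 (σ = 0.15), reflecting that the two pools are separate
multiplex PCR reactions. Residual count noise uses dispersion r = 400
(≈ 6.5% CV at 850X). Heterozygous variants alternate haplotypes read by read
(alt fraction exactly 0.5 before error); strands are i.i.d. at
`strand_balance`; substitution errors occur per base at `base_error_rate`
(0 by default — the cascade's thresholds, not a base-quality model, are the
object under test). Samples with the large deletion emit zero reads over the
deleted exons (copies = 1 would emit half depth); dropout regions silence
every amplicon that overlaps them. A count-only fast path
(`simulate_amplicon_counts`) draws from the same random stream the read
simulator uses, and a test pins the two paths equal; CNV experiments run on
it, which is what makes 20 × 30-sample cohorts cheap.

**What the simulator does not emulate.** Flow-space/homopolymer error
structure of semiconductor sequencing, base qualities, alignment artifacts,
barcode/adapter chemistry, allelic-balance skew, and real population LD.
Passing tests therefore demonstrate the *logic* of the pipeline — thresholds,
normalization, segmentation, parsing, arithmetic — under controlled noise,
not robustness to platform-specific artifacts.

## Coverage QC

Depth counts read bases aligned to a position: deleted read bases add no
depth (depth means base-callable evidence). A read is on-target if it
overlaps any target region by ≥ 1 base. Report metrics: mean target depth;
uniformity = fraction of target bases ≥ 0.2 × mean (the usual platform
convention; the source of the printed 0.95 is undefined, so a convention had
to be chosen); fraction of bases covered by *more than* 100 reads (strict,
per the wording it reproduces); and the gap list — maximal runs of target
bases under 50X, the minimum depth at which variant calling is attempted at
all. The gap worklist annotates each gap with overlapping exons, amplicons
and any catalog variants, i.e. the regions a lab would Sanger-fill. One
consequence of the depth definition: the interior of a homozygous deletion
call appears as a (true) zero-coverage mini-gap.

## Variant screen

Stranded pileup over target positions: insertion alleles are keyed to the
base before the event (folding that read's base call into the allele, so
site depth remains the sum of allele counts), deletions to their first
deleted base, both left-aligned on output. The cascade, evaluated per alt
allele:

| condition | status |
|---|---|
| site depth < 50 | `no_call_region` |
| 50 ≤ depth < 80 | reference-callable, alt evidence flagged `low_depth` |
| alt fraction < 20% | `low_fraction` |
| < 1 alt read on either strand | `single_strand` |
| otherwise | `PASS`; hom iff fraction ≥ 0.80, else het |

The hom/het boundary (0.80) and the one-read-per-strand minimum are
configurable conventions; the 20%/80X/50X thresholds are the screen's
defining constants. At most two alts can PASS at a site (diploid); extras are
flagged. The no-call BED equals the coverage-QC gap set computed from the
same reads, by construction (both derive from the same depth array and
threshold).

## Classification

Consequence is computed from gene geometry and the allele alone: codon-level
effect in coding exons (biopython translation), frameshift by indel length
mod 3, canonical splice = intronic positions 1–2 from an exon boundary,
noncanonical = 3–8, deeper = intronic. Tier rules in precedence order:

1. a mutation-database entry fixes the tier (previously described variants
   are annotated directly; if this overrides the truncating rule the output
   is flagged);
2. nonsense, frameshift, large rearrangements, canonical splice →
   definitely pathogenic;
3. missense / in-frame / noncanonical splice → vote over supplied predictor
   verdicts: ≥ 3/4 deleterious → likely pathogenic, ≤ 1/4 → neutral, else
   uncertain (as is anything with conflicting published evidence, or with no
   predictor data);
4. everything else without a database entry → neutral.

Predictor verdicts are packaged inputs, not computed — the real predictors
are third-party tools and a synthetic gene has no orthologous alignments to
feed them. The ¾ / ¼ vote cutoffs are a design choice (the classification
criteria in the source workflow list evidence types but no decision rule).
Common polymorphisms (population frequency ≥ 5%) are discarded from the
reported candidates unless the mutation database lists them; this filter is
applied to reporting only, *after* the concordance comparison, because the
validation's own truth set includes high-frequency neutral polymorphisms.

## Copy-number detection

Per-amplicon counts → RPKM (reads per kb of insert per million on-target
reads; read-to-amplicon assignment by maximal overlap, ties to the lower
index) → per-amplicon standardization across samples → thresholding and run
segmentation. The standardization is deliberately robust, because a single
homozygous 31-amplicon deletion is an enormous outlier at 30-sample scale and
naive choices each destroy the signal in a different way:

* **Size factors.** Each sample is rescaled by the median of its
  amplicon-wise ratios to the cohort median profile, excluding amplicons
  below 0.4× the profile. Without this, a sample that loses ~30% of its
  reads to a real deletion has every remaining amplicon inflated by
  per-million normalization (spurious gains), and the deleted amplicons
  themselves would drag the median.
* **Scale.** Centre = per-amplicon median; scale = 1.4826 × MAD, floored at
  10⁻⁶. An SD would be inflated by the carrier's own outlier, compressing
  its z-scores toward the threshold.
* **Component removal.** For cohorts ≥ 20 samples the top singular component
  is removed (the per-sample pool-imbalance mode); the component is
  estimated on a ±3-clipped copy of the z-matrix, then its projection is
  subtracted from the unclipped matrix. Estimated on the raw matrix, the
  top component *is* the deletion at this scale, and removing it erases the
  event.

Because the pool mode contributes most of each amplicon's cross-sample
variance but is removed from the values, residual noise sits near N(0, 0.67²)
while a homozygous deletion sits at z ≈ −10 and a single-copy loss near −5.
Detection thresholds are ±2.0 (≈ 3× the residual noise) with a minimum run of
3 consecutive outlier amplicons — on this panel any deletion spanning two
whole exons covers at least six amplicons, so the run requirement costs no
sensitivity while suppressing isolated noise pairs. A deletion run is called
homozygous when its mean raw RPKM is below 0.1× the cohort median. The
pipeline skips CNV calling below 8 samples: cross-sample standardization on a
handful of columns is noise. Measured operating point (seeded): the planted
exons 4–11 homozygous deletion is recovered with the exact span in 20/20
30-sample cohorts, with zero calls across CNV-free cohorts.

## TG-T diplotyping

Genotyping is sequence-level, not alignment-level: aligners compress repeat
indels, so coordinates inside the tract are ignored. Reads containing both
anchors are parsed with `anchor_left (TG)+ (T)+ anchor_right`; any
interruption, or an allele outside TG[9–14] × T[4–9], is a countable
parse-failure. (The supported grid is wider than the tract's clinical
TG[11–13]T[5–9] notation because alleles outside that notation are observed
in practice.) The top allele is always reported; a second allele needs ≥ 20%
of parsed reads (ties resolved toward the lexicographically lower (tg, t));
fewer than 10 parsed reads yields a gap-style no-call. Risk flags: `T5` for
any reported 5-T allele, plus `TG12_T5` / `TG13_T5` for the higher-risk
TG backgrounds (CBAVD-associated). A sample homozygous for a deletion
spanning exon 10 has no tract to read — the correct output is a no-call.

## Diagnostic validation

A truth variant is recovered only by a PASS call with identical left-aligned
(pos, ref, alt) *and* identical zygosity; anything else is a false negative
(annotated with whether its locus fell in a coverage gap). False positives
are PASS calls absent from truth; sites below the 50X callability floor are
not genotyped and can produce neither. The large deletion is matched by exon
span and copy state against the CNV calls. True negatives are counted per
genotyped target site per sample minus the variant-positive sites —
variant-level numerators over a site-level negative denominator, mirroring
how such screens report mixed-granularity counts.

Metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
NPV TN/(TN+FN). 95% CIs use the normal (SD-based) binomial approximation
when the error count is nonzero and the Wilson score interval (z = 1.96)
when it is zero, where the SD-based interval degenerates; for zero failures
the Wilson lower bound reduces algebraically to 1/(1 + z²/n). Percentages
are printed at two decimals, rounded half-up — except NPV, which is
truncated toward zero so that a 99.998% NPV reports as 99.99% rather than
inflating to 100% while false negatives exist.

## Problem sizes and determinism

Every stochastic stage consumes a `numpy` Generator seeded from one master
integer; per-sample streams derive from it by CRC-32 of the sample id, so
runs are reproducible file-for-file (the pipeline manifest records SHA-256
digests, and a test pins two same-seed runs digest-identical). The packaged
experiment sizes — 10 samples at 852X for end-to-end recovery, 20 × 30-sample
cohorts (count-level) for deletion recovery, the full 666-diplotype grid at
~160 spanning reads and 100 error trials at ~520 reads for the tract — were
chosen as the smallest scales at which each claim is meaningfully exercised.

## Known limitations

* Genotype calls are threshold-based; there are no genotype likelihoods or
  quality scores.
* The CNV caller reports one deletion/duplication state, not dosage, and has
  no breakpoint resolution; single-amplicon events are below its design
  floor by construction.
* cDNA (c.) labels are simplified HGVS-like strings for reporting, not
  validated nomenclature.
* The 0.4 ratio floor in size-factor estimation assumes a deletion does not
  span more than half the panel.
* Multi-allelic handling reports at most two PASS alleles and evaluates
  each alt independently; true multi-allelic genotype models are out of
  scope.
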