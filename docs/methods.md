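# Methods

## The system being modeled

*C. elegans* piRNAs (21U-RNAs) are 21-nt, 5′-uracil small RNAs bound by the
Piwi Argonaute PRG-1. Two locus classes exist: **motif-dependent** loci
carry the Ruby motif — an 8-nt core (consensus `CTGTTTCA`) whose 3′ end
lies ~40 bp upstream of the mature 5′U, separated by an A/T-rich spacer —
and **motif-independent** loci lack it. Each locus is transcribed by
Pol II into a short capped precursor that begins 2 nt upstream of the
mature 5′U and peaks at 28–29 nt, then is processed to the mature 21-mer.
The nuclear factor PRDE-1 is required specifically for motif-dependent
precursor production; PRG-1 is required downstream for mature piRNA
stability of both classes. Mature piRNAs direct synthesis of secondary
22G-RNAs (~22 nt, 5′G, antisense) at target genes, whose loss de-represses
the targets.

The package implements the informatics of this system and validates it on
a synthetic cohort whose generator encodes exactly the structural facts
above, with a truth set for recovery scoring.

## Synthetic-data generator

`SimConfig` defaults define the study conditions:

| parameter | default | why |
|---|---|---|
| `n_chrom`, `chrom_len` | 2 × 200 kb | one piRNA-cluster chromosome (all loci), one gene chromosome; large enough for non-overlapping placement, small enough for seconds-scale runs |
| `n_motif_loci` / `n_nonmotif_loci` | 300 / 60 | the motif class dominates, as in the real locus complement; desk-scale counts with enough motif-independent loci for rank tests |
| `motif_offset_mean` ± `motif_offset_jitter` | 40 ± 2 bp (triangular, mode 40) | "~40 bp" upstream placement with mild spacer-length variability |
| `spacer_at_fraction` | 0.75 | A/T-rich spacer |
| `precursor_ext5` | 2 nt (fixed) | capped precursors begin 2 nt upstream of the 5′U |
| `precursor_len_probs` | categorical on 26–36 nt, equal modes at 28/29, few > 34 | reproduces the 28–29 nt peak and the near-absence of species > 36 nt without asserting an unobserved 3′-end rule; the 3′ extension is length − 23 |
| `precursor_mature_ratio` | 0.15 | precursors are a minority of a TAP library relative to mature species; the absolute ratio is not pinned by data, so it is an exposed knob |
| `library_depth` | 200 000 | MiSeq-scale collapsed depth |
| `background_fraction` | 0.05 | degradation fragments (random genomic 15–35-mers) in every protocol |
| `genotype_effects` | wild type 1/1; *prg-1* mature 0, precursor 1; *prde-1* motif-dependent 0/0, motif-independent mature ×1.25, precursor 1 | the observed genotype structure; "almost completely absent" is modeled as multiplier 0 — residual reads come from the background fraction, which is also why residual species show no 2-nt extension peak; the ×1.25 uplift encodes "slightly increased" and is a config default, not a claim |
| `n_target_genes` | 60 (20 shared / 20 prg1-only / 20 untargeted) | enough genes per class for ≥ 90 % sensitivity bounds to be meaningful |
| `g22_depletion` | 0.1 | "clear reductions" of 22Gs at silenced-target genes |
| `g22_target_fraction` | 0.2 | targets are a minority of the total 22G pool, as in real libraries where 22Gs map genome-wide; this keeps RPM normalization from artificially inflating unaltered genes when target 22Gs are lost |
| `g22_prg1_only_weight` | 0.5 | prg-1-specific targets carry fewer wild-type 22Gs than shared targets |
| `expr_effect_log2`, `expr_noise_sd`, `n_reps` | +2.5, 0.4, 3 | array-scale effect and noise; three biological replicates |

Protocol filters: `untreated` (5′-monophosphate cloning) excludes capped
precursors; `TAP` includes them; `capRNA` contains only capped species
(mature excluded). Background degradation slices are present in all three
— real capRNA libraries also contain residual non-precursor reads.

The generator plants features by writing into the genome array
(strand-aware): the 5′U is forced to T, the core to its jittered offset,
the spacer drawn A/T-rich; motif-independent loci are resampled until no
core occurs within 60 bp upstream. Target genes receive one planted
antisense piRNA site (0–3 mismatches) — shared targets take a
motif-dependent piRNA, prg1-only targets a motif-independent one, matching
which piRNA class survives in each mutant — and a cluster of 22G start
sites around it whose genomic base is fixed so every 22G read begins with
G and still matches the genome exactly. All randomness derives from one
seed through named CRC-keyed substreams, so any stage can be rerun
byte-identically in isolation.

What the generator does **not** emulate: sequencing error, PCR
duplication, 2′-O-methylation chemistry, spliced transcripts, multimapping
repeat structure, off-cluster motif loci, and miRNA/other small-RNA
classes. Passing recovery tests therefore demonstrates correctness of the
pipeline's logic under the stated model, not robustness to real-library
artifacts.

## Motif model

The original scoring matrix behind the published cutoff is not available,
so the score is fully specified here: an 8-position core PWM, pseudocount
1, uniform background, scores in bits (log2-odds), maximized over core
3′-end offsets 30–50 bp upstream of the 5′U (±10 bp around the canonical
~40 bp to absorb spacer variability). Training extracts, per training
locus, the window 8-mer best matching the seed consensus `CTGTTTCA` (ties
toward offset 40, then smaller) — truth offsets are never used. Under
simulation this reproduces the operative behavior of the published score:
a planted-core population near 16 bits, a background population spanning
roughly −20 to +8 bits, clean separation at the strict `> 7` cutoff, and a
bimodal width-5 score histogram. Users holding an externally estimated
matrix can load it from TSV instead. Ties in the placement argmax break
toward offset 40, then the smaller offset; loci too close to a chromosome
end are scored over the placements that fit (with a warning) and are an
error only when no placement fits. The score deliberately covers the core
only, not spacer or flanking positions — the file-loading escape hatch
covers users who need a wider matrix.

## Precursor caller

Matching is locus-anchored rather than whole-genome: each read is tested
for exact genome identity at 5′ extensions 0–15 nt upstream of each
candidate locus 5′U (seeded by a 15-nt anchor index of mature prefixes).
This is bit-exact, alignment-free, and equivalent to a brute-force scan
(property-tested on ≤ 50 kb genomes). Guards: species with 5′ extension
> 10 nt or length > 45 nt are classed `other_locus_overlap` and excluded
from precursor profiles, keeping degradation fragments out of the
histograms. Multi-locus reads count toward each locus in per-locus tables
(flagged) but once in global histograms and the conservation ledger, so
modes are undistorted and per-class counts always sum to the library
total. Histogram modes report both read-weighted and unique-sequence
columns; ties break toward the smaller value for deterministic reporting.

## Abundance statistics

RPM uses the total library count (assigned + unassigned). The depletion
test is a one-sided Wilcoxon; the paired signed-rank form is the default
because loci are matched across genotypes (the unpaired rank-sum is a
flag). Exact null for ≤ 25 informative pairs, normal approximation with
continuity correction beyond; all-zero difference vectors give p = 1 by
convention with a warning. Fold changes add a 0.1-RPM pseudocount (stated
in output metadata) only for reporting — the test ranks raw values. Note
that because libraries are compositional, wholesale loss of the
motif-dependent class mechanically inflates the RPM of the surviving
motif-independent class well beyond its ×1.25 generative uplift; the
class summary reports what a sequencing experiment would actually show.

## Target analysis

* `find_targets`: ungapped Hamming matching of the piRNA reverse
  complement, mismatches over the full 21 nt, no G:U wobble (the stated
  rule is plain mismatch counting), verified against exhaustive
  enumeration.
* `antisense_22g`: reads 20–23 nt with 5′G (strictly 22 is a flag),
  exact antisense match fully inside the gene body, counted once per gene,
  RPM to total library size; per-position 5′-start profiles available.
* `de_gene_sets`: per mutant-vs-wild-type contrast, Welch t-test (safer
  than pooled variance at n = 3; a flag forces pooled), mean log2FC, and
  BH q-values across genes (the named correction is not specified
  upstream; BH is the field default). A gene **enters** the regulated
  universe when it passes all three gates — log2FC strictly above log2(4),
  p < 0.05, q < 0.1 — in at least one mutant contrast; entered genes are
  then **assigned** to shared / prg1-only / prde1-only by which contrasts
  show clear (> 2-fold) up-regulation. Requiring the full triple gate
  independently in every contrast was considered and rejected: with a
  +2.5 log2 effect, σ = 0.4, and three replicates, the strict-fold gate
  alone passes ~94 % per contrast, so a conjunctive rule caps shared-set
  sensitivity near 88 % and misses genes that are plainly up in both
  mutants but marginal in one; entry-by-any with pattern assignment keeps
  per-class sensitivity ~98 % at < 1 % cross-class leakage. Genotype
  labels starting with `prde1` form the prde-1 family, so two-allele
  designs work unchanged.
* 22G-based classification (analysis stage) calls a gene "reduced" below
  a twofold drop in antisense 22G RPM vs wild type — the midpoint in log
  space between the depleted mode (~0.1–0.4, lifted by background reads
  landing in gene bodies) and the unaltered mode (~1).
* `fisher_enrichment`: two-sided exact p via the hypergeometric
  distribution; sample odds ratio; zero-margin tables return p = 1 with an
  undefined odds ratio. `permutation_set_test`: mean set score against
  same-size random sets, p = (1 + exceedances) / (n_perm + 1).
  `rank_set_compare`: two-sided Mann–Whitney, exact when untied and both
  n ≤ 25, tie-corrected asymptotic otherwise; fully tied input gives
  p = 1 with a warning.

## Numerical and design choices

* Coordinates are 0-based half-open throughout; a locus `start` is the
  genomic coordinate of the mature 5′ base on either strand (a minus-strand
  locus stores interval end − 1), which makes 5′-extension arithmetic
  strand-uniform.
* Genomes may contain N; loci overlapping N are rejected with a warning
  and PWM placements containing N are skipped (exact-match and log-odds
  semantics are undefined over N).
* The classification cutoff (> 7) is strict, matching its definition; a
  score of exactly 7 is motif-independent.
* Score histogram bins are `[5k, 5k+5)` indexed by midpoint; mode counting
  compresses equal-count plateaus and treats zero bins as separators.
* All mode reports break ties toward the smaller value.

## Problem sizes

Default conditions (360 loci on 200 kb, 200 000 reads per library, 60
genes, 3 replicates) run each analysis script in seconds and the full test
suite — including 1 000-replicate type-I-error calibration of the Wilcoxon
test and the exhaustive-oracle property suites — in well under a minute.
Unit tests use a reduced cohort (75 loci on 40 kb, 30 000 reads);
class-recovery bounds are always checked at the default conditions, where
they are stated.

## Known limitations

* Exact matching only: a single sequencing error unassigns a read, so
  real-library recovery would be lower than the synthetic bounds.
* The PWM scores the 8-mer core only; motifs with informative flanks
  require an externally supplied matrix.
* Gene models are unspliced single-interval bodies; 22G quantification
  over real annotations with introns/UTRs would need interval stitching.
* The expression stage consumes a processed log2 matrix; array/RNA-seq
  normalization is out of scope.
* One *prde-1* genotype is generated by default; the published two-allele
  design is supported by the analysis code but not exercised by the
  default cohort.
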