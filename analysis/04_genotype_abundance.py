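#!/usr/bin/env python
"""Genotype-wise piRNA abundance: RPM tables, class-wise fold changes, and
one-sided Wilcoxon depletion tests.

Uses the untreated (5'-monophosphate-dependent) libraries, i.e. mature
piRNAs, split by the motif classes assigned in the scoring stage: prg-1
should deplete both classes, prde-1 only the motif-dependent class.
"""

from pathlib import Path

import pirnaforge as pf

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "sim"
OUT = BASE / "abundance"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = pf.read_fasta(SIM / "genome.fa")
    loci = pf.read_loci(BASE / "motif" / "scored.bed", genome)

    alignments = {}
    totals = {}
    genotypes = {}
    for genotype in ("wild_type", "prg1", "prde1"):
        sample = f"{genotype}_untreated"
        lib = pf.read_library(SIM / f"{sample}.tsv", sample, genotype,
                              "untreated")
        alignments[sample] = pf.assign_reads(lib, genome, loci)
        totals[sample] = lib.total_count
        genotypes[sample] = genotype

    counts = pf.locus_count_table(alignments, [l.locus_id for l in loci])
    rpm = pf.normalize_rpm(counts, totals)
    counts.to_csv(OUT / "mature_counts.tsv", sep="\t")
    rpm.to_csv(OUT / "mature_rpm.tsv", sep="\t", float_format="%.4f")

    classes = {l.locus_id: l.class_label for l in loci}
    summary = pf.class_summary(rpm, classes, genotypes)
    summary.to_csv(OUT / "class_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print("\nreading the table: motif-dependent piRNAs collapse in both "
          "mutants, while the\nmotif-independent class persists in prde-1 "
          "(fold change >= 1, one-sided p = 1).")


if __name__ == "__main__":
    main()
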