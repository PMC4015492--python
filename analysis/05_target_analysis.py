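#!/usr/bin/env python
"""Downstream target analysis: DE gene sets, antisense 22G quantification,
piRNA target prediction, and enrichment statistics.

Builds the up-regulated gene sets from the expression matrix (fold > 4,
p < 0.05, BH q < 0.1 in at least one mutant contrast), quantifies antisense
22G-RNAs per gene and genotype, predicts piRNA target sites allowing up to
three mismatches, and tests whether piRNA-targeted genes are enriched in
the DE sets (Fisher exact + permutation gene-set test).
"""

from pathlib import Path

import pandas as pd

import pirnaforge as pf

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "sim"
OUT = BASE / "targets"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = pf.read_fasta(SIM / "genome.fa")
    loci = pf.read_loci(BASE / "motif" / "scored.bed", genome)
    genes = pf.read_genes(SIM / "genes.bed")
    truth = pd.read_csv(SIM / "truth_gene_classes.tsv", sep="\t",
                        index_col="gene_id")["true_class"]

    # differential expression
    expr = pf.io_formats.read_expression(SIM / "expr.tsv")
    sets = pf.de_gene_sets(expr)
    rows = [(g, s) for s, members in
            (("shared", sets.shared), ("prg1_only", sets.prg1_only),
             ("prde1_only", sets.prde1_only), ("other", sets.other))
            for g in members]
    de_frame = pd.DataFrame(rows, columns=["gene_id", "de_set"])
    de_frame.to_csv(OUT / "de_sets.tsv", sep="\t", index=False)
    shared_truth = set(truth.index[truth == "shared_target"])
    prg1_truth = set(truth.index[truth == "prg1_only_target"])
    print(f"DE sets: shared {len(sets.shared)} "
          f"({len(set(sets.shared) & shared_truth)}/{len(shared_truth)} "
          f"truth recovered), prg1_only {len(sets.prg1_only)} "
          f"({len(set(sets.prg1_only) & prg1_truth)}/{len(prg1_truth)}), "
          f"prde1_only {len(sets.prde1_only)}, other {len(sets.other)}")

    # antisense 22G quantification per genotype
    quant = {}
    for genotype in ("wild_type", "prg1", "prde1"):
        lib = pf.read_library(SIM / f"{genotype}_22g.tsv",
                              f"{genotype}_22g", genotype, "untreated")
        quant[genotype] = pf.antisense_22g(lib, genes, genome)
    ratios = pd.DataFrame({
        g: (quant[g]["rpm"] + 0.1) / (quant["wild_type"]["rpm"] + 0.1)
        for g in ("prg1", "prde1")
    })
    ratios["true_class"] = truth
    ratios.to_csv(OUT / "g22_ratios.tsv", sep="\t", float_format="%.4f")
    med = ratios.groupby("true_class")[["prg1", "prde1"]].median()
    print("\nmedian 22G RPM ratio vs wild type by truth class:")
    print(med.round(3).to_string())

    # piRNA target prediction (<= 3 mismatches, antisense)
    transcripts = pf.gene_transcripts(genes, genome)
    hits = []
    for locus in loci:
        for h in pf.find_targets(locus.mature_seq, transcripts,
                                 pirna_id=locus.locus_id):
            hits.append((h.pirna_id, h.gene_id, h.position, h.mismatches))
    hits_frame = pd.DataFrame(
        hits, columns=["pirna_id", "gene_id", "position", "mismatches"])
    hits_frame.to_csv(OUT / "target_hits.tsv", sep="\t", index=False)
    targeted = set(hits_frame["gene_id"])

    # enrichment of piRNA-targeted genes in the shared DE set
    universe = [g.gene_id for g in genes]
    in_set = set(sets.shared)
    odds, p_fisher = pf.fisher_enrichment(
        len(in_set & targeted), len(in_set),
        len(targeted & set(universe)), len(universe))
    pct_set = 100 * len(in_set & targeted) / max(len(in_set), 1)
    pct_all = 100 * len(targeted & set(universe)) / len(universe)
    print(f"\npiRNA-targeted: {pct_set:.0f}% of shared DE genes vs "
          f"{pct_all:.0f}% of all genes "
          f"(Fisher OR {odds:.1f}, p = {p_fisher:.2g})")

    # permutation gene-set test on the prde-1 contrast statistic
    gene_stat = sets.table[("prde1", "log2fc")]
    p_perm = pf.permutation_set_test(gene_stat, sets.shared, n_perm=999,
                                     seed=7)
    print(f"permutation gene-set test, shared set on prde-1 log2FC: "
          f"p = {p_perm:.4f}")

    # wild-type 22G levels: prg-1-specific targets carry fewer 22Gs
    wt = quant["wild_type"]["rpm"]
    u, p_rank = pf.rank_set_compare(wt[list(shared_truth)],
                                    wt[list(prg1_truth)])
    print(f"wild-type 22G RPM, shared vs prg1-only targets: "
          f"medians {wt[list(shared_truth)].median():.0f} vs "
          f"{wt[list(prg1_truth)].median():.0f}, "
          f"Wilcoxon unpaired p = {p_rank:.3g}")


if __name__ == "__main__":
    main()
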