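#!/usr/bin/env python
"""Score every piRNA locus with the Ruby-core PWM and classify at cutoff 7.

Trains the 8-position core matrix on half of the loci that the generator
marked motif-dependent (training uses only sequence, not truth offsets),
scores all loci over the 30-50 bp upstream window, writes the scored BED
and the width-5 score histogram, and reports classification accuracy
against generator truth.
"""

from pathlib import Path

import pandas as pd

import pirnaforge as pf

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "sim"
OUT = BASE / "motif"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = pf.read_fasta(SIM / "genome.fa")
    loci = pf.read_loci(SIM / "loci.bed", genome)
    truth = pd.read_csv(SIM / "truth_locus_classes.tsv", sep="\t",
                        index_col="locus_id")["true_class"]

    train = [l for l in loci if truth[l.locus_id] == "motif_dependent"][::2]
    pwm = pf.build_pwm(pf.extract_training_cores(genome, train))
    print(f"PWM trained on {len(train)} loci; consensus {pwm.consensus}, "
          f"consensus score {pwm.consensus_score():.2f} bits")

    offsets = []
    for locus in loci:
        ms = pf.score_locus(genome, locus, pwm)
        locus.motif_score = ms.score
        locus.class_label = pf.classify_locus(ms)
        if truth[locus.locus_id] == "motif_dependent":
            offsets.append(ms.offset)
    pf.write_loci(loci, OUT / "scored.bed", scored=True)

    hist = pf.score_histogram([l.motif_score for l in loci])
    hist.rename_axis("window_midpoint").to_csv(OUT / "score_histogram.tsv",
                                               sep="\t")
    accuracy = sum(l.class_label == truth[l.locus_id] for l in loci) / len(loci)
    modal_offset = max(sorted(set(offsets)), key=offsets.count)
    md_scores = [l.motif_score for l in loci
                 if truth[l.locus_id] == "motif_dependent"]
    mi_scores = [l.motif_score for l in loci
                 if truth[l.locus_id] == "motif_independent"]
    print(f"score distribution: planted-core population at "
          f"{min(md_scores):.1f}..{max(md_scores):.1f} bits, background "
          f"population at {min(mi_scores):.1f}..{max(mi_scores):.1f} bits "
          f"({pf.count_modes(hist)} histogram modes)")
    print(f"classification accuracy vs truth at cutoff 7: {accuracy:.3f}")
    print(f"modal core offset across motif-dependent loci: {modal_offset} bp "
          f"(canonical ~40 bp upstream of the 5'U)")


if __name__ == "__main__":
    main()
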