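#!/usr/bin/env python
"""Generate the synthetic study cohort under the default conditions.

Writes genome, piRNA locus and gene annotations, nine small-RNA libraries
(wild-type / prg-1 / prde-1 x untreated / TAP / capRNA), per-genotype 22G
libraries, the replicated expression matrix, and the generator truth tables
to results/sim/.
"""

from pathlib import Path

from pirnaforge.cli import _simulate
from pirnaforge.synthetic_data import SimConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 7


def main() -> None:
    config = SimConfig(seed=SEED)
    _simulate(config, OUT)
    print(f"cohort written to {OUT}")
    print(f"  {config.n_motif_loci} motif-dependent + "
          f"{config.n_nonmotif_loci} motif-independent loci, "
          f"{config.n_target_genes} target genes, "
          f"depth {config.library_depth} reads/library, seed {SEED}")


if __name__ == "__main__":
    main()
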