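"""piRNA target prediction, 22G-RNA quantification, differential-expression
gene sets, and the enrichment statistics over them.

Target prediction slides the reverse complement of a piRNA along each
transcript and reports every ungapped window within the mismatch bound
(default 3, plain Hamming distance, no G:U wobble).  22G-RNAs are
operationalized as reads of length 20-23 with a 5' guanine matching the
genome exactly in antisense orientation within a gene body, normalized to
total library size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, GeneInterval, GenomeSequence, \
    Library, revcomp

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "U": 3}


@dataclass
class TargetHit:
    """An ungapped antisense complementarity site of a piRNA on a transcript."""

    pirna_id: str
    gene_id: str
    position: int  # 0-based start of the site on the transcript
    mismatches: int
    orientation: str = "antisense"


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE[b] for b in seq.upper()], dtype=np.int8)


def find_targets(
    pirna_seq: str,
    transcripts: dict[str, str],
    max_mm: int = 3,
    pirna_id: str = "piRNA",
) -> list[TargetHit]:
    """All ungapped antisense sites with Hamming distance <= max_mm.

    The reverse complement of the piRNA is compared against every window of
    each transcript; mismatches are counted over the full piRNA length.
    A transcript shorter than the piRNA yields no hits.
    """
    probe = _encode(revcomp(pirna_seq.upper().replace("U", "T")))
    k = len(probe)
    hits: list[TargetHit] = []
    for gene_id, transcript in transcripts.items():
        enc = _encode(transcript)
        n = len(enc) - k + 1
        if n <= 0:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, k)
        mm = (windows != probe).sum(axis=1)
        for pos in np.nonzero(mm <= max_mm)[0]:
            hits.append(TargetHit(pirna_id, gene_id, int(pos), int(mm[pos])))
    return hits


def gene_transcripts(
    genes: list[GeneInterval], genome: dict[str, GenomeSequence]
) -> dict[str, str]:
    """Spliced-naive transcript sequences (gene body on the gene strand)."""
    out = {}
    for g in genes:
        raw = genome[g.chrom].seq[g.start:g.end]
        out[g.gene_id] = raw if g.strand == "+" else revcomp(raw)
    return out


# ---------------------------------------------------------------------------
# 22G quantification
# ---------------------------------------------------------------------------

def antisense_22g(
    library: Library,
    genes: list[GeneInterval],
    genome: dict[str, GenomeSequence],
    length_range: tuple[int, int] = (20, 23),
    require_5g: bool = True,
    with_profiles: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, dict[int, int]]]:
    """Per-gene antisense 22G-RNA counts and RPM.

    A read qualifies if its length is within ``length_range``, it starts
    with G (when ``require_5g``), and it matches the genome exactly in
    antisense orientation fully within the gene body.  A read is counted
    once per gene; RPM is relative to the total library size.  With
    ``with_profiles`` the per-gene 5'-start position histogram (genomic
    coordinates, count-weighted) is returned as well.
    """
    for g in genes:
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.gene_id}: unstranded annotation")
    total = library.total_count
    candidates = [
        (seq, count) for seq, count in library.reads.items()
        if length_range[0] <= len(seq) <= length_range[1]
        and (not require_5g or seq.startswith("G"))
    ]
    counts = {g.gene_id: 0 for g in genes}
    profiles: dict[str, dict[int, int]] = {g.gene_id: {} for g in genes}
    for gene in genes:
        body = genome[gene.chrom].seq[gene.start:gene.end]
        for seq, count in candidates:
            # antisense to a + gene means the read maps on the - strand:
            # its reverse complement appears on the sense sequence
            probe = revcomp(seq) if gene.strand == "+" else seq
            idx = body.find(probe)
            if idx < 0:
                continue
            counts[gene.gene_id] += count
            if with_profiles:
                if gene.strand == "+":
                    start5 = gene.start + idx + len(seq) - 1
                else:
                    start5 = gene.start + idx
                prof = profiles[gene.gene_id]
                prof[start5] = prof.get(start5, 0) + count
    frame = pd.DataFrame({
        "count": pd.Series(counts),
        "rpm": pd.Series({g: c / total * 1e6 for g, c in counts.items()}),
    })
    frame.index.name = "gene_id"
    if with_profiles:
        return frame, profiles
    return frame


# ---------------------------------------------------------------------------
# Differential-expression gene sets
# ---------------------------------------------------------------------------

@dataclass
class DEGeneSets:
    """Classified up-regulated gene sets from mutant-vs-wild-type contrasts.

    A gene enters the universe of regulated genes when it passes all three
    gates (log2FC strictly above log2(fold), t-test p < alpha, BH q <
    mt_alpha) in at least one mutant contrast; entered genes are then
    assigned to shared / prg1_only / prde1_only by which contrasts show
    clear up-regulation (log2FC above log2(pattern_fold)).
    """

    shared: list[str] = field(default_factory=list)
    prg1_only: list[str] = field(default_factory=list)
    prde1_only: list[str] = field(default_factory=list)
    other: list[str] = field(default_factory=list)
    table: pd.DataFrame | None = None
    thresholds: dict = field(default_factory=dict)


def de_gene_sets(
    expr: ExpressionMatrix,
    fold: float = 4.0,
    alpha: float = 0.05,
    mt_alpha: float = 0.1,
    pattern_fold: float = 2.0,
    baseline: str = "wild_type",
    equal_var: bool = False,
) -> DEGeneSets:
    """Build the up-regulated gene sets from a replicated expression matrix.

    Per mutant genotype vs the baseline: mean log2 fold change, two-sample
    t-test (Welch by default; ``equal_var=True`` forces pooled variance),
    and Benjamini-Hochberg q-values across genes.  Genotypes whose label
    starts with ``prde1`` form the prde-1 family; ``shared`` requires clear
    up-regulation in prg1 and every prde-1 genotype.
    """
    wt_cols = expr.genotype_columns(baseline)
    if len(wt_cols) < 2:
        raise ValueError("need >= 2 baseline replicates")
    mutants = [g for g in expr.genotypes if g != baseline]
    genes = expr.values.index
    stats_frames = {}
    for genotype in mutants:
        cols = expr.genotype_columns(genotype)
        if len(cols) < 2:
            raise ValueError(f"need >= 2 replicates for {genotype}")
        mut_vals = expr.values[cols].to_numpy()
        wt_vals = expr.values[wt_cols].to_numpy()
        lfc = mut_vals.mean(axis=1) - wt_vals.mean(axis=1)
        t, p = stats.ttest_ind(mut_vals, wt_vals, axis=1,
                               equal_var=equal_var)
        q = multipletests(p, method="fdr_bh")[1]
        stats_frames[genotype] = pd.DataFrame(
            {"log2fc": lfc, "p": p, "q": q}, index=genes)

    log2_fold = np.log2(fold)
    log2_pattern = np.log2(pattern_fold)
    passes = pd.DataFrame(index=genes)
    up = pd.DataFrame(index=genes)
    for genotype, frame in stats_frames.items():
        passes[genotype] = (
            (frame["log2fc"] > log2_fold)
            & (frame["p"] < alpha)
            & (frame["q"] < mt_alpha)
        )
        up[genotype] = frame["log2fc"] > log2_pattern

    entered = passes.any(axis=1)
    prde1_family = [g for g in mutants if g.startswith("prde1")]
    has_prg1 = "prg1" in mutants
    sets = DEGeneSets(thresholds={
        "fold": fold, "alpha": alpha, "mt_alpha": mt_alpha,
        "pattern_fold": pattern_fold, "equal_var": equal_var,
    })
    for gene in genes[entered]:
        up_prg1 = has_prg1 and bool(up.loc[gene, "prg1"])
        up_prde1_all = bool(prde1_family) and all(
            up.loc[gene, g] for g in prde1_family)
        up_prde1_any = any(up.loc[gene, g] for g in prde1_family)
        if up_prg1 and up_prde1_all:
            sets.shared.append(gene)
        elif up_prg1 and not up_prde1_any:
            sets.prg1_only.append(gene)
        elif up_prde1_any and not up_prg1:
            sets.prde1_only.append(gene)
        else:
            sets.other.append(gene)

    table = pd.concat(
        {g: f for g, f in stats_frames.items()}, axis=1)
    table[("summary", "entered")] = entered
    sets.table = table
    return sets


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

def fisher_enrichment(
    hits_in_set: int,
    set_size: int,
    hits_in_universe: int,
    universe_size: int,
) -> tuple[float, float]:
    """Two-sided Fisher's exact test on set membership vs the hit property.

    Returns the sample odds ratio and exact p-value (hypergeometric
    enumeration).  A zero-margin table has an undefined odds ratio and
    p = 1.
    """
    if not (0 <= hits_in_set <= set_size <= universe_size):
        raise ValueError("inconsistent counts")
    if not (hits_in_set <= hits_in_universe <= universe_size):
        raise ValueError("inconsistent counts")
    if hits_in_universe - hits_in_set > universe_size - set_size:
        raise ValueError("inconsistent counts")
    a = hits_in_set
    b = set_size - hits_in_set
    c = hits_in_universe - hits_in_set
    d = (universe_size - set_size) - c
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero-margin table: odds ratio undefined, p = 1",
                      stacklevel=2)
        return float("nan"), 1.0
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def permutation_set_test(
    gene_stat: pd.Series,
    gene_set: list[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the mean score of a gene set.

    Null sets of the same size are drawn without replacement from the
    scored universe; p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    missing = [g for g in gene_set if g not in gene_stat.index]
    if missing:
        raise ValueError(f"gene set members not scored: {missing[:5]}")
    k = len(gene_set)
    if k == 0 or k > len(gene_stat):
        raise ValueError("gene set must be non-empty and within the universe")
    observed = float(gene_stat.loc[gene_set].mean())
    values = gene_stat.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        null = values[rng.choice(len(values), size=k, replace=False)].mean()
        if null >= observed:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def rank_set_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction.

    Returns (U statistic for the first sample, p).  Fully tied data yields
    p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if len(np.unique(np.concatenate([a, b]))) == 1:
        warnings.warn("all values tied; p = 1", stacklevel=2)
        return float(len(a) * len(b) / 2), 1.0
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and max(len(a), len(b)) <= 25) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
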