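"""Library normalization and genotype-wise depletion statistics.

Abundances are normalized to reads per million of *total* library size
(RPM), not only assigned reads.  Depletion relative to wild type is tested
with a one-sided Wilcoxon test; loci are natural pairs across genotypes, so
the paired signed-rank form is the default (the unpaired rank-sum is
available via ``paired=False``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .precursor_caller import ReadAlignment

FOLD_CHANGE_PSEUDOCOUNT_RPM = 0.1


def locus_count_table(
    alignments_by_sample: dict[str, list[ReadAlignment]],
    locus_ids: list[str],
    species: str = "mature",
) -> pd.DataFrame:
    """Per-locus read counts (one species class) across samples.

    Multi-locus reads count toward every matching locus, consistent with the
    per-locus tables of :func:`..precursor_caller.per_locus_counts`.
    """
    table = pd.DataFrame(0, index=pd.Index(locus_ids, name="locus_id"),
                         columns=list(alignments_by_sample), dtype=int)
    for sample, alignments in alignments_by_sample.items():
        for aln in alignments:
            if aln.species_call == species and aln.locus_id in table.index:
                table.loc[aln.locus_id, sample] += aln.count
    return table


def normalize_rpm(counts: pd.DataFrame, totals: dict[str, int]) -> pd.DataFrame:
    """counts / total library size x 1e6, per sample column."""
    rpm = counts.astype(float).copy()
    for sample in rpm.columns:
        total = totals[sample]
        if total <= 0:
            raise ValueError(f"sample {sample}: zero library total")
        rpm[sample] = rpm[sample] / total * 1e6
    return rpm


@dataclass
class ReductionResult:
    statistic: float
    p_value: float
    direction: str  # "reduction", "increase", or "none"
    n: int
    method: str


def reduction_test(
    wt: np.ndarray,
    mut: np.ndarray,
    paired: bool = True,
    exact_max_n: int = 25,
) -> ReductionResult:
    """One-sided Wilcoxon test for mut < wt.

    Paired (signed-rank) by default; exact null distribution for n <=
    ``exact_max_n`` non-zero pairs, normal approximation with continuity
    correction otherwise.  All-zero differences yield p = 1 by convention
    with a warning.
    """
    wt = np.asarray(wt, dtype=float)
    mut = np.asarray(mut, dtype=float)
    if paired:
        if len(wt) != len(mut):
            raise ValueError("paired test requires equal-length vectors")
        diffs = mut - wt
        nonzero = int(np.count_nonzero(diffs))
        if nonzero == 0:
            warnings.warn("all paired differences are zero; p = 1 by "
                          "convention", stacklevel=2)
            return ReductionResult(0.0, 1.0, "none", len(wt),
                                   "wilcoxon_signed_rank")
        method = "exact" if nonzero <= exact_max_n else "approx"
        res = stats.wilcoxon(mut, wt, alternative="less",
                             zero_method="wilcox", correction=True,
                             method=method)
        stat, p = float(res.statistic), float(res.pvalue)
        label = f"wilcoxon_signed_rank_{method}"
        n = nonzero
    else:
        res = stats.mannwhitneyu(mut, wt, alternative="less")
        stat, p = float(res.statistic), float(res.pvalue)
        label = "mann_whitney_u"
        n = len(mut)
    med_wt, med_mut = float(np.median(wt)), float(np.median(mut))
    if med_mut < med_wt:
        direction = "reduction"
    elif med_mut > med_wt:
        direction = "increase"
    else:
        direction = "none"
    return ReductionResult(stat, p, direction, n, label)


def class_summary(
    rpm: pd.DataFrame,
    locus_classes: dict[str, str],
    sample_genotypes: dict[str, str],
    baseline: str = "wild_type",
) -> pd.DataFrame:
    """Per (motif class, genotype): median RPM, median fold change vs the
    baseline genotype, and the one-sided depletion p-value.

    Fold changes use a pseudocount of 0.1 RPM (the test itself runs on the
    raw RPM values; ranks handle zeros).  Classes with fewer than 10 loci
    are reported with ``low_power=True``.
    """
    genotype_cols: dict[str, list[str]] = {}
    for sample, genotype in sample_genotypes.items():
        genotype_cols.setdefault(genotype, []).append(sample)
    if baseline not in genotype_cols:
        raise ValueError(f"no samples with baseline genotype {baseline!r}")
    classes = pd.Series(
        {loc: locus_classes.get(loc, "unscored") for loc in rpm.index})
    pc = FOLD_CHANGE_PSEUDOCOUNT_RPM
    rows = []
    for cls in sorted(classes.unique()):
        loci = classes[classes == cls].index
        base_vals = rpm.loc[loci, genotype_cols[baseline]].mean(axis=1)
        for genotype, cols in genotype_cols.items():
            vals = rpm.loc[loci, cols].mean(axis=1)
            fold = (vals + pc) / (base_vals + pc)
            if genotype == baseline:
                p = np.nan
            else:
                p = reduction_test(base_vals.to_numpy(),
                                   vals.to_numpy()).p_value
            rows.append({
                "class_label": cls,
                "genotype": genotype,
                "n_loci": len(loci),
                "median_rpm": float(vals.median()),
                "median_fold_change": float(fold.median()),
                "p_reduction": p,
                "low_power": len(loci) < 10,
            })
    summary = pd.DataFrame(rows)
    if summary["low_power"].any():
        low = summary.loc[summary["low_power"], "class_label"].unique()
        warnings.warn(f"classes with < 10 loci (low power): {list(low)}",
                      stacklevel=2)
    return summary
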