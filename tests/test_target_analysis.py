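"""Target prediction, 22G quantification, DE sets, and enrichment statistics
against exhaustive / closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

import pirnaforge as pf
from pirnaforge.io_formats import ExpressionMatrix
from pirnaforge.target_analysis import de_gene_sets


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestFindTargets:
    def test_exact_reverse_complement_zero_mismatches(self):
        pirna = "TGGTACGTACGTACGTACGTA"
        transcript = "A" * 30 + pf.revcomp(pirna) + "C" * 30
        hits = pf.find_targets(pirna, {"g1": transcript})
        assert [(h.gene_id, h.position, h.mismatches) for h in hits] == \
            [("g1", 30, 0)]

    def test_four_mismatches_not_reported(self):
        pirna = "T" * 21
        site = list(pf.revcomp(pirna))
        for i in (0, 5, 10, 15):
            site[i] = "C"  # A -> C: four mismatches
        transcript = "G" * 10 + "".join(site) + "G" * 10
        assert pf.find_targets(pirna, {"g1": transcript}, max_mm=3) == []
        assert len(pf.find_targets(pirna, {"g1": transcript}, max_mm=4)) >= 1

    def test_transcript_shorter_than_pirna_no_hits(self):
        assert pf.find_targets("T" * 21, {"g1": "ACGT"}) == []

    def test_u_treated_as_t(self):
        pirna = "UGGUACGUACGUACGUACGUA"
        transcript = pf.revcomp(pirna.replace("U", "T"))
        assert len(pf.find_targets(pirna, {"g1": transcript})) == 1

    @given(st.text(alphabet="ACGT", min_size=21, max_size=21),
           st.text(alphabet="ACGT", min_size=10, max_size=200),
           st.integers(min_value=0, max_value=3))
    def test_matches_exhaustive_enumeration(self, pirna, transcript, max_mm):
        """Hit list equals brute-force enumeration of every window."""
        probe = pf.revcomp(pirna)
        expected = [
            (pos, _hamming(probe, transcript[pos:pos + 21]))
            for pos in range(len(transcript) - 20)
            if _hamming(probe, transcript[pos:pos + 21]) <= max_mm
        ]
        hits = pf.find_targets(pirna, {"g": transcript}, max_mm=max_mm)
        assert [(h.position, h.mismatches) for h in hits] == expected


@pytest.fixture(scope="module")
def g22_quant(default_sim):
    """22G libraries, expression matrix, and per-gene quantification under
    the default study conditions (class-recovery bounds are stated there)."""
    genome, _, truth = default_sim
    libs, expr = pf.generate_22g_and_expression(truth, seed=61)
    quant = {
        g: pf.antisense_22g(libs[f"{g}_22g"], truth.genes, genome)
        for g in ("wild_type", "prg1", "prde1")
    }
    return truth, libs, expr, quant


class TestAntisense22G:
    def test_sense_reads_not_counted(self, small_sim):
        genome, _, truth = small_sim
        gene = truth.genes[0]
        body = genome[gene.chrom].seq[gene.start:gene.end]
        # a sense-orientation read: the transcript's own sequence
        sense = body[10:32] if gene.strand == "+" else pf.revcomp(body[10:32])
        sense = "G" + sense[1:]  # satisfy the 5'G filter
        lib = pf.Library("s", "wild_type", "untreated", {sense: 5})
        frame = pf.antisense_22g(lib, [gene], genome)
        assert frame.loc[gene.gene_id, "count"] == 0

    def test_antisense_read_counted_with_profile(self, small_sim):
        genome, _, truth = small_sim
        gene = truth.genes[0]
        site = truth.g22_sites[gene.gene_id][0]
        window = genome[gene.chrom].seq[site:site + 22]
        read = pf.revcomp(window) if gene.strand == "+" else window
        assert read[0] == "G"
        lib = pf.Library("s", "wild_type", "untreated", {read: 4})
        frame, profiles = pf.antisense_22g(lib, [gene], genome,
                                           with_profiles=True)
        assert frame.loc[gene.gene_id, "count"] == 4
        expected_start = site + 21 if gene.strand == "+" else site
        assert profiles[gene.gene_id] == {expected_start: 4}

    def test_unstranded_gene_rejected(self, small_sim):
        genome, _, truth = small_sim
        gene = truth.genes[0]
        bad = pf.GeneInterval(gene.gene_id, gene.chrom, gene.start, gene.end,
                              "+")
        bad.strand = "."
        lib = pf.Library("s", "wild_type", "untreated", {"G" * 22: 1})
        with pytest.raises(ValueError, match="unstranded"):
            pf.antisense_22g(lib, [bad], genome)

    def test_shared_targets_depleted_prg1_only_unaltered_in_prde1(
            self, g22_quant):
        truth, _, _, quant = g22_quant
        cls = pd.Series(truth.gene_classes)
        ratio = (quant["prde1"]["rpm"] + 0.1) / \
            (quant["wild_type"]["rpm"] + 0.1)
        assert ratio[cls == "shared_target"].median() < 0.3
        assert 0.5 < ratio[cls == "prg1_only_target"].median() < 2.0

    def test_prg1_only_targets_have_fewer_22g_in_wildtype(self, g22_quant):
        """Rank comparison of wild-type 22G levels between target classes."""
        truth, _, _, quant = g22_quant
        cls = pd.Series(truth.gene_classes)
        wt = quant["wild_type"]["rpm"]
        shared = wt[cls == "shared_target"]
        prg1_only = wt[cls == "prg1_only_target"]
        _, p = pf.rank_set_compare(shared, prg1_only)
        assert shared.median() > prg1_only.median()
        assert p < 0.05


class TestDeGeneSets:
    @staticmethod
    def _matrix(values, genotypes):
        columns = []
        labels = []
        for g, reps in genotypes:
            for r in range(reps):
                columns.append(f"{g}_r{r + 1}")
                labels.append(g)
        frame = pd.DataFrame(values, columns=columns,
                             index=[f"g{i}" for i in range(len(values))])
        samples = pd.DataFrame({
            "sample_id": columns, "genotype": labels,
            "replicate": [1] * len(columns),
        })
        return ExpressionMatrix(values=frame, samples=samples)

    def test_exact_fourfold_is_excluded(self):
        """'More than fourfold' is strict: a noise-free gene at exactly
        log2FC = 2 never enters."""
        base = [1.0, 1.001, 0.999]
        up4 = [3.0, 3.001, 2.999]  # exactly +2 in log2 vs base means
        up9 = [5.2, 5.201, 5.199]
        expr = self._matrix(
            [base + up4, base + up9],
            [("wild_type", 3), ("prg1", 3)],
        )
        sets = de_gene_sets(expr)
        assert "g0" not in (sets.shared + sets.prg1_only + sets.other)
        assert "g1" in sets.prg1_only

    def test_recovers_generator_gene_classes(self, g22_quant):
        """>= 90% sensitivity per truth class with <= 5% cross-class
        leakage at the default effect size."""
        truth, _, expr, _ = g22_quant
        sets = de_gene_sets(expr)
        shared_truth = {g for g, c in truth.gene_classes.items()
                        if c == "shared_target"}
        prg1_truth = {g for g, c in truth.gene_classes.items()
                      if c == "prg1_only_target"}
        assert len(set(sets.shared) & shared_truth) >= 0.9 * len(shared_truth)
        assert len(set(sets.prg1_only) & prg1_truth) >= 0.9 * len(prg1_truth)
        leak = (len(set(sets.shared) & prg1_truth)
                + len(set(sets.prg1_only) & shared_truth))
        assert leak <= 0.05 * (len(shared_truth) + len(prg1_truth))
        untargeted = {g for g, c in truth.gene_classes.items()
                      if c == "untargeted"}
        assert not untargeted & set(sets.shared + sets.prg1_only)

    def test_permuted_labels_give_empty_sets(self, g22_quant):
        truth, _, expr, _ = g22_quant
        rng = np.random.default_rng(67)
        shuffled = expr.samples.copy()
        shuffled["genotype"] = rng.permutation(shuffled["genotype"])
        permuted = ExpressionMatrix(values=expr.values, samples=shuffled)
        sets = de_gene_sets(permuted)
        assert len(sets.shared + sets.prg1_only + sets.prde1_only
                   + sets.other) <= 1

    def test_bh_q_values_dominate_p_and_are_monotone(self, g22_quant):
        truth, _, expr, _ = g22_quant
        sets = de_gene_sets(expr)
        for genotype in ("prg1", "prde1"):
            sub = sets.table[genotype].sort_values("p")
            assert (sub["q"] >= sub["p"] - 1e-12).all()
            assert sub["q"].is_monotonic_increasing


class TestFisherEnrichment:
    def test_balanced_table_no_association(self):
        odds, p = pf.fisher_enrichment(10, 20, 20, 40)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_perfect_separation_matches_enumeration(self):
        """Table (5,0 / 0,5): p from full hypergeometric support."""
        odds, p = pf.fisher_enrichment(5, 5, 5, 10)
        rv = hypergeom(10, 5, 5)
        support = np.arange(0, 6)
        pmf = rv.pmf(support)
        expected = pmf[pmf <= pmf[5] * (1 + 1e-9)].sum()
        assert p == pytest.approx(expected)
        assert np.isinf(odds)

    def test_proportional_doubling_keeps_odds_ratio(self):
        odds1, _ = pf.fisher_enrichment(8, 20, 14, 60)
        odds2, _ = pf.fisher_enrichment(16, 40, 28, 120)
        assert odds1 == pytest.approx(odds2)

    def test_zero_margin_table(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            odds, p = pf.fisher_enrichment(0, 10, 0, 20)
        assert np.isnan(odds)
        assert p == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            pf.fisher_enrichment(11, 10, 12, 20)


class TestPermutationSetTest:
    def test_top_k_set_reaches_floor(self):
        stat = pd.Series(np.arange(100, dtype=float),
                         index=[f"g{i}" for i in range(100)])
        top = [f"g{i}" for i in range(95, 100)]
        p = pf.permutation_set_test(stat, top, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_same_seed_same_p(self):
        rng = np.random.default_rng(8)
        stat = pd.Series(rng.normal(size=200),
                         index=[f"g{i}" for i in range(200)])
        gene_set = [f"g{i}" for i in range(0, 200, 10)]
        p1 = pf.permutation_set_test(stat, gene_set, n_perm=500, seed=9)
        p2 = pf.permutation_set_test(stat, gene_set, n_perm=500, seed=9)
        assert p1 == p2

    def test_null_calibration(self):
        """Random sets give roughly uniform p-values."""
        rng = np.random.default_rng(10)
        stat = pd.Series(rng.normal(size=300),
                         index=[f"g{i}" for i in range(300)])
        ps = []
        for i in range(200):
            gene_set = list(stat.sample(15, random_state=i).index)
            ps.append(pf.permutation_set_test(stat, gene_set, n_perm=199,
                                              seed=i))
        ps = np.asarray(ps)
        assert 0.4 < ps.mean() < 0.6
        assert 0.03 < (ps < 0.1).mean() < 0.2

    def test_set_outside_universe_rejected(self):
        stat = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="not scored"):
            pf.permutation_set_test(stat, ["z"], n_perm=100)


class TestRankSetCompare:
    def test_all_tied_is_null(self):
        with pytest.warns(UserWarning, match="tied"):
            _, p = pf.rank_set_compare([3.0] * 10, [3.0] * 12)
        assert p == 1.0

    def test_disjoint_support_matches_exact_enumeration(self):
        """n=m=20 with disjoint support: two-sided p = 2 / C(40, 20)."""
        a = np.arange(1, 21, dtype=float)
        b = np.arange(100, 120, dtype=float)
        _, p = pf.rank_set_compare(a, b)
        from math import comb
        assert p == pytest.approx(2 / comb(40, 20), rel=1e-9)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 25)
        b = rng.normal(1, 1, 30)
        ua, pa = pf.rank_set_compare(a, b)
        ub, pb = pf.rank_set_compare(b, a)
        assert pa == pytest.approx(pb)
        assert ua + ub == pytest.approx(len(a) * len(b))
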