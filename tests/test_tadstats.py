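"""TAD enrichment, homogeneity, fold-change correlation and bivalency."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from gliotad.core import GenomicInterval, TadSegment
from gliotad.promoters import TadAssignment, assign_genes_to_tads
from gliotad.tadstats import (
    bivalent_genes,
    kw_homogeneity,
    permutation_homogeneity,
    tad_enrichment,
    tad_fc_correlation,
    tad_overlap_hypergeom,
)

from conftest import make_matrix


def make_assignment(tad_sizes):
    """TadAssignment with tad i holding tad_sizes[i] genes g<t>_<j>."""
    gene_to_tad, tad_to_genes = {}, {}
    for t, size in enumerate(tad_sizes):
        tid = f"t{t}"
        genes = [f"g{t}_{j}" for j in range(size)]
        tad_to_genes[tid] = genes
        for g in genes:
            gene_to_tad[g] = tid
    return TadAssignment(gene_to_tad, tad_to_genes)


def binom_upper_tail(k, n, p):
    """Brute-force pmf summation P(X >= k)."""
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


class TestTadEnrichment:
    def test_matches_hand_computed_tail(self):
        # one 5-gene TAD with 3 flagged; global background tuned to 0.1
        # via a 95-gene filler TAD holding the remaining 7 flags
        assignment = make_assignment([5, 95])
        flagged = {"g0_0", "g0_1", "g0_2"} | {f"g1_{j}" for j in range(7)}
        recs = {r.tad_id: r for r in tad_enrichment(assignment, flagged)}
        assert recs["t0"].background_prob == pytest.approx(0.1)
        assert recs["t0"].p_raw == pytest.approx(0.00856, abs=5e-6)

    def test_zero_flagged_gives_p_one(self):
        assignment = make_assignment([5, 5])
        recs = {r.tad_id: r
                for r in tad_enrichment(assignment, {"g1_0"})}
        assert recs["t0"].p_raw == pytest.approx(1.0)

    def test_small_tads_excluded_before_bh(self):
        assignment = make_assignment([2, 10, 10])
        flagged = {"g0_0", "g0_1", "g1_0"}
        recs = {r.tad_id: r for r in tad_enrichment(assignment, flagged)}
        assert recs["t0"].p_raw is None
        assert not recs["t0"].enriched
        assert recs["t1"].p_raw is not None

    def test_flagged_outside_tads_dropped(self):
        assignment = make_assignment([5, 5])
        recs = tad_enrichment(assignment, {"g0_0", "not_a_gene"})
        assert all(r.background_prob == pytest.approx(0.1) for r in recs)

    def test_p_raw_matches_brute_force_everywhere(self):
        rng = np.random.default_rng(11)
        sizes = rng.integers(3, 40, size=60)
        assignment = make_assignment(sizes)
        flagged = {
            g for g in assignment.gene_to_tad if rng.random() < 0.15
        }
        bg = len(flagged) / sum(sizes)
        for r in tad_enrichment(assignment, flagged):
            assert r.p_raw == pytest.approx(
                binom_upper_tail(r.n_flagged, r.n_genes, bg), abs=1e-12
            )


class TestHomogeneity:
    def test_all_equal_values(self):
        a = make_assignment([2, 2])
        res = kw_homogeneity({g: 1.5 for g in a.gene_to_tad}, a)
        assert res.statistic == 0.0 and res.p_asymptotic == 1.0

    def test_two_group_statistic(self):
        # groups (1,2) and (3,4): H = 12/(4*5) * (2*1 + 2*1) = 2.4
        a = make_assignment([2, 2])
        fc = {"g0_0": 1, "g0_1": 2, "g1_0": 3, "g1_1": 4}
        res = kw_homogeneity(fc, a)
        assert res.statistic == pytest.approx(2.4)

    def test_matches_scipy_kruskal(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        a = make_assignment([5, 8, 3, 6])
        fc = {g: float(rng.normal()) for g in a.gene_to_tad}
        res = kw_homogeneity(fc, a)
        groups = [[fc[g] for g in a.genes_in(t)] for t in a.tad_to_genes]
        expected = stats.kruskal(*groups)
        assert res.statistic == pytest.approx(expected.statistic)
        assert res.p_asymptotic == pytest.approx(expected.pvalue)

    def test_single_group_errors(self):
        a = make_assignment([4])
        with pytest.raises(ValueError):
            kw_homogeneity({g: 1.0 for g in a.gene_to_tad}, a)

    def test_permutation_p_estimator_never_zero(self):
        rng = np.random.default_rng(0)
        a = make_assignment([10, 10, 10])
        # strongly structured: each TAD its own level
        fc = {}
        for t, tid in enumerate(a.tad_to_genes):
            for g in a.genes_in(tid):
                fc[g] = float(t) + float(rng.normal(0, 0.01))
        res = permutation_homogeneity(fc, a, n_perm=200, rng=rng)
        assert res.p_permutation == pytest.approx(1 / 201)

    def test_invariant_under_monotone_transform_and_relabel(self):
        a = make_assignment([6, 6, 6])
        rng = np.random.default_rng(9)
        fc = {g: float(rng.normal()) for g in a.gene_to_tad}
        res1 = permutation_homogeneity(fc, a, n_perm=300,
                                       rng=np.random.default_rng(1))
        fc2 = {g: np.exp(v) for g, v in fc.items()}  # monotone transform
        res2 = permutation_homogeneity(fc2, a, n_perm=300,
                                       rng=np.random.default_rng(1))
        assert res1.statistic == pytest.approx(res2.statistic)
        assert res1.p_permutation == pytest.approx(res2.p_permutation)
        relabelled = TadAssignment(
            {g: "x" + t for g, t in a.gene_to_tad.items()},
            {"x" + t: gs for t, gs in a.tad_to_genes.items()},
        )
        res3 = permutation_homogeneity(fc, relabelled, n_perm=300,
                                       rng=np.random.default_rng(1))
        assert res3.statistic == pytest.approx(res1.statistic)

    def test_nperm_zero_rejected(self):
        a = make_assignment([2, 2])
        with pytest.raises(ValueError):
            permutation_homogeneity({g: 1.0 for g in a.gene_to_tad}, a,
                                    n_perm=0)


class TestTadFcCorrelation:
    def test_perfect_and_inverted(self):
        a = make_assignment([3, 3, 3, 3])
        expr = {g: float(i) for i, g in enumerate(sorted(a.gene_to_tad))}
        mark_same = dict(expr)
        _, rho = tad_fc_correlation(expr, mark_same, a)
        assert rho == pytest.approx(1.0)
        mark_neg = {g: -v for g, v in expr.items()}
        _, rho = tad_fc_correlation(expr, mark_neg, a)
        assert rho == pytest.approx(-1.0)

    def test_too_few_tads_errors(self):
        a = make_assignment([3, 3])
        expr = {g: 1.0 for g in a.gene_to_tad}
        with pytest.raises(ValueError, match="TADs"):
            tad_fc_correlation(expr, expr, a)


class TestBivalentGenes:
    def _matrices(self, k4_order, k27_order, n_samples=3):
        ids = sorted(set(k4_order) | set(k27_order))
        k4_rank = {g: i for i, g in enumerate(k4_order)}
        k27_rank = {g: i for i, g in enumerate(k27_order)}
        k4 = [[len(ids) - k4_rank.get(g, len(ids))] * n_samples for g in ids]
        k27 = [[len(ids) - k27_rank.get(g, len(ids))] * n_samples
               for g in ids]
        samples = [f"s{j}" for j in range(n_samples)]
        return (make_matrix(k4, ids, samples, "H3K4me3"),
                make_matrix(k27, ids, samples, "H3K27me3"))

    def test_membership_rules(self):
        genes = [f"g{i}" for i in range(6)]
        k4, k27 = self._matrices(genes, genes)
        # top-2 in both marks, intersected with degs
        assert bivalent_genes(k4, k27, {"g0", "g5"}, top_n=2) == {"g0"}
        # top in one mark only is excluded
        k4b, k27b = self._matrices(genes, list(reversed(genes)))
        assert bivalent_genes(k4b, k27b, set(genes), top_n=2) == set()

    def test_structured_fixture_recovers_spiked_size(self):
        # 2000 genes; top-1000 sets overlap in 1000 genes of which 54 are
        # DEGs -> output has exactly those 54
        genes = [f"g{i:04d}" for i in range(2000)]
        k4_order = genes[:1000] + genes[1000:]        # top: 0..999
        k27_order = genes[:1000][::-1] + genes[1000:]  # top: 0..999 too
        k4, k27 = self._matrices(k4_order, k27_order)
        degs = set(genes[100:154])
        out = bivalent_genes(k4, k27, degs, top_n=1000)
        assert out == degs and len(out) == 54

    def test_top_n_larger_than_gene_count(self):
        genes = [f"g{i}" for i in range(4)]
        k4, k27 = self._matrices(genes, genes)
        assert bivalent_genes(k4, k27, set(genes), top_n=100) == set(genes)


class TestTadOverlapHypergeom:
    def test_hand_computed_example(self):
        universe = {f"t{i}" for i in range(10)}
        enriched = {"t0", "t1", "t2", "t3"}
        marked = {"t0", "t1", "t9"}
        # P(X >= 2) = (C(4,2)C(6,1) + C(4,3)C(6,0)) / C(10,3) = 40/120
        assert tad_overlap_hypergeom(enriched, marked, universe) == (
            pytest.approx(1 / 3)
        )

    def test_zero_overlap_gives_one(self):
        universe = {f"t{i}" for i in range(6)}
        assert tad_overlap_hypergeom({"t0"}, {"t5"}, universe) <= 1.0
        assert tad_overlap_hypergeom(set(), {"t5"}, universe) == (
            pytest.approx(1.0)
        )

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(21)
        for n_universe in (5, 8, 12):
            universe = [f"t{i}" for i in range(n_universe)]
            for _ in range(5):
                enr = set(rng.choice(universe,
                                     size=int(rng.integers(1, n_universe)),
                                     replace=False))
                n_marked = int(rng.integers(1, n_universe))
                marked = set(rng.choice(universe, size=n_marked,
                                        replace=False))
                obs = len(enr & marked)
                total = hits = 0
                for subset in combinations(universe, n_marked):
                    total += 1
                    if len(enr & set(subset)) >= obs:
                        hits += 1
                assert tad_overlap_hypergeom(enr, marked, set(universe)) == (
                    pytest.approx(hits / total, abs=1e-12)
                )

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty"):
            tad_overlap_hypergeom(set(), set(), set())
        with pytest.raises(ValueError, match="subset"):
            tad_overlap_hypergeom({"a"}, set(), {"b"})
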