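"""Enhancer calling, contact linking and enhancer-level statistics."""

import numpy as np
import pandas as pd
import pytest

from gliotad.core import (
    ContactPair,
    GeneAnnotation,
    GenomicInterval,
    MethylationRecord,
    SampleSheet,
)
from gliotad.enhancers import (
    Enhancer,
    call_enhancers,
    compare_expression_by_class,
    contact_classes,
    correlation_permutation_null,
    differential_region_signal,
    enhancer_methylation,
    link_correlations,
    link_genes_to_enhancers,
)
from gliotad.promoters import make_promoters

from conftest import make_matrix


def promoters_at(*tss):
    genes = [GeneAnnotation(f"g{i}", "chr1", "+", t)
             for i, t in enumerate(tss)]
    return make_promoters(genes, 2000)


class TestCallEnhancers:
    def test_promoter_overlap_rules(self):
        proms = promoters_at(10_000)  # promoter [8000, 12000)
        peaks = [
            (GenomicInterval("chr1", 9000, 9100), {"s": 1.0}),   # inside
            (GenomicInterval("chr1", 22_000, 23_000), {"s": 1.0}),  # 10 kb away
            (GenomicInterval("chr1", 11_999, 12_500), {"s": 1.0}),  # 1 bp over
            (GenomicInterval("chr1", 12_000, 12_500), {"s": 1.0}),  # touching
        ]
        enh = call_enhancers(peaks, proms)
        starts = {e.interval.start for e in enh}
        assert starts == {22_000, 12_000}  # any-overlap excludes, touch kept


class TestLinking:
    def _setup(self):
        proms = promoters_at(10_000)  # midpoint 10000
        enhancers = [
            Enhancer("e_near", GenomicInterval("chr1", 1_009_000, 1_011_000),
                     {}),  # ~1 Mb away
            Enhancer("e_far", GenomicInterval("chr1", 2_509_000, 2_511_000),
                     {}),  # 2.5 Mb away
        ]
        return proms, enhancers

    def test_basic_link_and_distance_filter(self):
        proms, enhancers = self._setup()
        contacts = [
            ContactPair(GenomicInterval("chr1", 9_000, 9_100),
                        GenomicInterval("chr1", 1_009_500, 1_009_600)),
            ContactPair(GenomicInterval("chr1", 9_000, 9_100),
                        GenomicInterval("chr1", 2_509_500, 2_509_600)),
        ]
        links = link_genes_to_enhancers(proms, enhancers, contacts)
        assert [(l.gene_id, l.enhancer_id, l.n_contacts) for l in links] == [
            ("g0", "e_near", 1)
        ]

    def test_orientation_and_dedup(self):
        proms, enhancers = self._setup()
        contacts = [
            # promoter anchor second, enhancer anchor first
            ContactPair(GenomicInterval("chr1", 1_009_500, 1_009_600),
                        GenomicInterval("chr1", 9_000, 9_100)),
            ContactPair(GenomicInterval("chr1", 8_500, 8_600),
                        GenomicInterval("chr1", 1_010_000, 1_010_100)),
        ]
        links = link_genes_to_enhancers(proms, enhancers, contacts)
        assert [(l.gene_id, l.enhancer_id, l.n_contacts) for l in links] == [
            ("g0", "e_near", 2)
        ]

    def test_brute_force_agreement_on_synthetic_cohort(self, small_cohort):
        cohort = small_cohort
        proms = make_promoters(cohort.genes, 2000)
        enhancers = [Enhancer(eid, iv, {}) for eid, iv in cohort.enhancers]
        links = link_genes_to_enhancers(proms, enhancers, cohort.contacts)
        # O(genes x enhancers x contacts) matcher
        expected = {}
        for g, prom in proms.items():
            for e in enhancers:
                if e.interval.chrom != prom.chrom:
                    continue
                if abs(prom.midpoint - e.interval.midpoint) > 2_000_000:
                    continue
                n = 0
                for c in cohort.contacts:
                    for pa, ea in ((c.anchor_a, c.anchor_b),
                                   (c.anchor_b, c.anchor_a)):
                        if pa.overlaps(prom) and ea.overlaps(e.interval):
                            n += 1
                if n:
                    expected[(g, e.enhancer_id)] = n
        assert {(l.gene_id, l.enhancer_id): l.n_contacts
                for l in links} == expected
        assert len(expected) > 0


class TestContactClasses:
    def test_published_boundaries(self):
        from gliotad.enhancers import GeneEnhancerLink

        links = [
            GeneEnhancerLink("multi", "e1", 3),
            GeneEnhancerLink("multi", "e2", 3),   # total 6 -> multi
            GeneEnhancerLink("few", "e3", 5),     # total 5 -> few
        ]
        classes = contact_classes(links)
        assert classes["multi"] == (6, "multi")
        assert classes["few"] == (5, "few")
        assert "absent" not in classes

    def test_expression_comparison(self):
        mat = make_matrix(
            np.arange(6, dtype=float)[:, None] + 1,
            [f"g{i}" for i in range(6)], ["s1"],
        )
        classes = {
            "g0": (6, "multi"), "g1": (7, "multi"), "g2": (8, "multi"),
            "g3": (1, "few"), "g4": (2, "few"), "g5": (3, "few"),
        }
        # means: multi (1,2,3), few (4,5,6) -> complete separation, p = 0.1
        p, medians = compare_expression_by_class(mat, classes)
        assert p == pytest.approx(0.1)
        assert medians == {"multi": 2.0, "few": 5.0}
        with pytest.raises(ValueError):
            compare_expression_by_class(mat, {"g0": (6, "multi")})


class TestDifferentialRegions:
    def _sheet(self):
        ids = [f"PA{i}" for i in range(6)] + [f"GBM{i}" for i in range(6)]
        return SampleSheet(ids, ["PA"] * 6 + ["GBM"] * 6)

    def test_flat_region_not_significant(self):
        sheet = self._sheet()
        df = pd.DataFrame([[3.0] * 12], index=["r"],
                          columns=sheet.sample_ids)
        sig, p = differential_region_signal(df, sheet, "PA", "GBM")
        assert sig == set() and p["r"] == 1.0

    def test_alpha_boundary_is_strict(self):
        # complete separation at 3 vs 3 attains exactly p = 0.1; an alpha
        # of exactly 0.1 must NOT call it (strict <)
        sheet = SampleSheet(["a", "b", "c", "d", "e", "f"],
                            ["PA"] * 3 + ["GBM"] * 3)
        df = pd.DataFrame([[1.0, 2, 3, 10, 11, 12]], index=["r"],
                          columns=sheet.sample_ids)
        sig_at, p = differential_region_signal(df, sheet, "PA", "GBM",
                                               alpha=0.1)
        assert p["r"] == pytest.approx(0.1) and sig_at == set()
        sig_above, _ = differential_region_signal(df, sheet, "PA", "GBM",
                                                  alpha=0.11)
        assert sig_above == {"r"}

    def test_separated_region_called(self):
        sheet = self._sheet()
        df = pd.DataFrame([[1.0] * 6 + [50.0] * 6], index=["r"],
                          columns=sheet.sample_ids)
        sig, p = differential_region_signal(df, sheet, "PA", "GBM", 0.01)
        assert sig == {"r"} and p["r"] < 0.01


class TestEnhancerMethylation:
    def test_mean_and_missing(self):
        enh = Enhancer("e", GenomicInterval("chr1", 100, 200), {})
        recs = [
            MethylationRecord("chr1", 110, "s1", 0.2),
            MethylationRecord("chr1", 150, "s1", 0.4),
            MethylationRecord("chr1", 500, "s1", 0.9),  # outside
        ]
        out = enhancer_methylation(recs, enh, ["s1", "s2"])
        assert out["s1"] == pytest.approx(0.3)
        assert np.isnan(out["s2"])

    def test_simulated_anticorrelation(self, small_cohort):
        from gliotad.correlation import spearman

        cohort = small_cohort
        samples = cohort.samples.sample_ids
        rhos = []
        for eid, iv in cohort.enhancers[:20]:
            enh = Enhancer(eid, iv, {})
            beta = enhancer_methylation(cohort.methylation, enh, samples)
            acet = cohort.enhancer_acetylation.loc[eid, samples]
            rho = spearman(beta.to_numpy(), acet.to_numpy())
            if not np.isnan(rho):
                rhos.append(rho)
        assert np.median(rhos) < 0


class TestLinkCorrelations:
    def test_identical_vectors_and_constant(self):
        from gliotad.enhancers import GeneEnhancerLink

        expr = make_matrix([[1, 2, 3, 4]], ["g"], list("abcd"))
        acet = pd.DataFrame([[1, 2, 3, 4], [5, 5, 5, 5]],
                            index=["e1", "e2"], columns=list("abcd"))
        sheet = SampleSheet(list("abcd"), ["PA"] * 4)
        links = [GeneEnhancerLink("g", "e1", 1),
                 GeneEnhancerLink("g", "e2", 1)]
        out = link_correlations(links, expr, acet, sheet)
        rho = dict(zip(out["enhancer_id"], out["rho_all"]))
        assert rho["e1"] == pytest.approx(1.0)
        assert np.isnan(rho["e2"])


class TestPermutationNull:
    def test_single_rep_and_degenerate(self):
        e = np.array([[1.0, 2, 3, 4], [4, 3, 2, 1]])
        means = correlation_permutation_null(e, e.copy(), reps=1,
                                             rng=np.random.default_rng(0))
        assert means.shape == (1,)
        ident = np.tile([1.0, 2, 3, 4], (3, 1))
        means = correlation_permutation_null(ident, ident.copy(), reps=5,
                                             rng=np.random.default_rng(0))
        assert np.allclose(means, 1.0)  # every pairing correlates perfectly

    def test_needs_two_links(self):
        v = np.array([[1.0, 2, 3]])
        with pytest.raises(ValueError):
            correlation_permutation_null(v, v, reps=10)
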