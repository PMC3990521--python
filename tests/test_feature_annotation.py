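import numpy as np
import pytest

from occupeak.feature_annotation import (
    CATEGORIES,
    AnnotationIndex,
    CategoryComparison,
    category_binomial_test,
    category_enrichment_table,
    classify_location,
    compare_category_between_sets,
    genome_category_fractions,
    tss_distance_histogram,
)
from occupeak.genome_io import GeneModel, GenomeLayout, GenomicInterval, Peak, PeakSet


@pytest.fixture
def toy_layout():
    return GenomeLayout([("chr1", 20_000)])


@pytest.fixture
def toy_genes(toy_layout):
    return [
        GeneModel("gx", "chr1", "+", 3000, 9000, 4000, 8000,
                  ((3000, 5000), (6000, 9000))),
        # gy's promoter (upstream of its minus-strand TSS at 13999) overlaps
        # nothing; its tts window [9900,10000) abuts gx's intron region
        GeneModel("gy", "chr1", "-", 10_000, 14_000, 10_500, 13_500,
                  ((10_000, 11_000), (12_000, 14_000))),
    ]


def naive_labeler(genes, layout, promoter_up=1000, tts_down=1000):
    """Per-base exhaustive labeler built directly from the category
    definitions; the independent oracle for the indexed classifier."""
    labels = {}
    for chrom, L in layout:
        arr = [6] * L  # intergenic
        order = {c: i for i, c in enumerate(CATEGORIES)}
        for g in genes:
            if g.chrom != chrom:
                continue
            feats = [
                ("promoter", [g.promoter(promoter_up)]),
                ("tts", [g.tts_region(tts_down)]),
                ("utr5", g.utr5_blocks()),
                ("utr3", g.utr3_blocks()),
                ("exon", g.coding_exon_blocks()),
                ("intron", g.intron_blocks()),
            ]
            for cat, ivs in feats:
                for s, e in ivs:
                    for b in range(max(0, s), min(L, e)):
                        if order[cat] < arr[b]:
                            arr[b] = order[cat]
        labels[chrom] = arr
    return labels


class TestClassifyLocation:
    def test_intergenic_is_catch_all(self, toy_genes, toy_layout):
        index = AnnotationIndex(toy_genes, toy_layout)
        assert classify_location("chr1", 19_000, index) == "intergenic"

    def test_upstream_window_is_promoter(self, toy_genes, toy_layout):
        index = AnnotationIndex(toy_genes, toy_layout)
        assert classify_location("chr1", 2500, index) == "promoter"  # 500 bp upstream

    def test_promoter_beats_intron_of_other_gene(self, toy_layout):
        # position inside gene A's intron and gene B's promoter window
        genes = [
            GeneModel("a", "chr1", "+", 1000, 9000, 1000, 9000,
                      ((1000, 2000), (8000, 9000))),
            GeneModel("b", "chr1", "+", 5000, 7000, 5000, 7000, ((5000, 7000),)),
        ]
        index = AnnotationIndex(genes, toy_layout)
        assert classify_location("chr1", 4500, index) == "promoter"

    def test_matches_per_base_oracle_everywhere(self, toy_genes, toy_layout):
        index = AnnotationIndex(toy_genes, toy_layout)
        oracle = naive_labeler(toy_genes, toy_layout)["chr1"]
        got = index.classify_many("chr1", np.arange(20_000))
        want = np.array(CATEGORIES)[np.array(oracle)]
        assert (got == want).all()

    def test_classify_many_agrees_with_scalar(self, toy_genes, toy_layout):
        index = AnnotationIndex(toy_genes, toy_layout)
        pos = np.random.default_rng(0).integers(0, 20_000, size=300)
        many = index.classify_many("chr1", pos)
        assert all(m == index.classify("chr1", int(p)) for m, p in zip(many, pos))


class TestGenomeFractions:
    def test_empty_annotation_all_intergenic(self, toy_layout):
        frac = genome_category_fractions([], toy_layout)
        assert frac["intergenic"] == 1.0

    def test_fractions_sum_to_one(self, toy_genes, toy_layout):
        frac = genome_category_fractions(toy_genes, toy_layout)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_point_classification_per_base(self, toy_genes, toy_layout):
        # painting path and query path must agree exactly
        frac = genome_category_fractions(toy_genes, toy_layout)
        index = AnnotationIndex(toy_genes, toy_layout)
        got = index.classify_many("chr1", np.arange(20_000))
        for cat in CATEGORIES:
            assert frac[cat] == pytest.approx((got == cat).mean(), abs=1e-12)


class TestCategoryBinomial:
    def test_zero_successes_greater_tail_is_one(self):
        assert category_binomial_test(0, 10, 0.3, "greater") == 1.0

    def test_all_successes_closed_form(self):
        assert category_binomial_test(7, 7, 0.2, "greater") == pytest.approx(0.2**7)

    def test_matches_pmf_summation(self):
        from math import comb

        n, p0 = 25, 0.17
        for k in range(n + 1):
            pmf = [comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
            assert category_binomial_test(k, n, p0, "greater") == pytest.approx(
                sum(pmf[k:]), rel=1e-9
            )
            assert category_binomial_test(k, n, p0, "less") == pytest.approx(
                sum(pmf[: k + 1]), rel=1e-9
            )

    def test_degenerate_background_rejected(self):
        with pytest.raises(ValueError):
            category_binomial_test(1, 2, 1.0)


class TestEnrichmentTable:
    def test_folds_and_counts(self, toy_genes, toy_layout):
        index = AnnotationIndex(toy_genes, toy_layout)
        peaks = [
            Peak(GenomicInterval("chr1", 2400, 2600), 2500, 1.0),   # promoter
            Peak(GenomicInterval("chr1", 18_900, 19_100), 19_000, 1.0),  # intergenic
        ]
        rows = category_enrichment_table(PeakSet("t", peaks), index)
        by_cat = {r.category: r for r in rows}
        assert by_cat["promoter"].n_peaks == 1
        assert by_cat["promoter"].peak_fraction == 0.5
        assert by_cat["promoter"].fold == pytest.approx(
            0.5 / by_cat["promoter"].genome_fraction
        )
        assert sum(r.peak_fraction for r in rows) == pytest.approx(1.0)

    def test_empty_set_rejected(self, toy_genes, toy_layout):
        index = AnnotationIndex(toy_genes, toy_layout)
        with pytest.raises(ValueError, match="empty"):
            category_enrichment_table(PeakSet("e", [], total_mapped_reads=1), index)


class TestBetweenSetComparison:
    def test_null_configuration_not_significant(self):
        cc = CategoryComparison(m=100, n=100, m_prime=20, n_prime=20)
        assert compare_category_between_sets(cc) >= 0.25  # both tails >= 0.5

    def test_extreme_split_exact_value(self):
        cc = CategoryComparison(m=10, n=10, m_prime=10, n_prime=0)
        # f = 0.5; tails are P(X>=10)=0.5^10 and P(X<=0)=0.5^10
        assert compare_category_between_sets(cc) == pytest.approx(0.5**20, rel=1e-9)

    def test_monotone_in_frequency_gap(self):
        last = 2.0
        for d in range(0, 31, 5):
            cc = CategoryComparison(m=100, n=100, m_prime=50 + d, n_prime=50 - d)
            p = compare_category_between_sets(cc)
            assert p <= last + 1e-12
            last = p

    def test_boundary_frequencies_give_one(self):
        assert compare_category_between_sets(
            CategoryComparison(10, 10, 0, 0)
        ) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            CategoryComparison(m=5, n=5, m_prime=6, n_prime=0)


class TestTssHistogram:
    def test_peak_on_tss_lands_in_first_downstream_bin(self, toy_layout):
        genes = [GeneModel("g", "chr1", "+", 5000, 8000, 5000, 8000, ((5000, 8000),))]
        ps = PeakSet("t", [Peak(GenomicInterval("chr1", 4900, 5100), 5000, 1.0)])
        edges, counts = tss_distance_histogram(ps, genes, 500, 2000)
        bin_of_zero = int(np.searchsorted(edges, 0, side="right")) - 1
        assert counts[bin_of_zero] == 1 and counts.sum() == 1
        assert edges[bin_of_zero] == 0

    def test_strand_aware_sign(self):
        genes = [GeneModel("g", "chr1", "-", 5000, 8000, 5000, 8000, ((5000, 8000),))]
        # center at 8300 is 300 bp *upstream* of the minus-strand TSS (7999)
        ps = PeakSet("t", [Peak(GenomicInterval("chr1", 8200, 8400), 8300, 1.0)])
        edges, counts = tss_distance_histogram(ps, genes, 500, 2000)
        idx = np.nonzero(counts)[0]
        assert len(idx) == 1 and edges[idx[0]] == -500  # bin [-500, 0)

    def test_mass_conservation_within_range(self, sim):
        edges, counts = tss_distance_histogram(
            sim.peakset_a, sim.genes, 500, 10_000_000
        )
        # range far exceeds chromosome length: every peak lands in a bin
        assert counts.sum() == len(sim.peakset_a)

    def test_no_genes_rejected(self, sim):
        with pytest.raises(ValueError, match="no genes"):
            tss_distance_histogram(sim.peakset_a, [], 500, 1000)

    def test_symmetric_peaks_give_symmetric_histogram(self):
        rng = np.random.default_rng(5)
        genes = [
            GeneModel("g", "chr1", "+", 50_000, 60_000, 50_000, 60_000,
                      ((50_000, 60_000),))
        ]
        offsets = rng.integers(-4000, 4000, size=2000)
        peaks = [
            Peak(GenomicInterval("chr1", 50_000 + o - 100, 50_000 + o + 100),
                 50_000 + o, 1.0)
            for o in offsets
        ]
        edges, counts = tss_distance_histogram(PeakSet("s", peaks), genes, 1000, 4000)
        left, right = counts[: len(counts) // 2].sum(), counts[len(counts) // 2 :].sum()
        assert abs(left - right) / counts.sum() < 0.1
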