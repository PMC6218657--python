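"""Enrichment statistics, gene association and distribution comparisons."""

import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from atacdyn.enrichment import (
    GeneModel,
    accessibility_correlation,
    annotate_genomic_context,
    assign_regions_to_genes,
    binomial_enrichment,
    compare_lfc_distributions,
    fisher_enrichment,
    known_motif_enrichment,
    overlap_proportion,
    regulatory_domains,
)
from atacdyn.regions import GenomicInterval, IntervalSet


def iset(triples, prefix="x"):
    return IntervalSet(
        GenomicInterval(c, s, e, name=f"{prefix}{i}")
        for i, (c, s, e) in enumerate(triples)
    )


class TestOverlapProportion:
    def test_examples(self):
        q = iset([("chr1", 0, 100), ("chr1", 200, 300), ("chr1", 400, 500),
                  ("chr1", 600, 700)])
        assert overlap_proportion(q, q) == 1.0
        far = iset([("chr2", 0, 100)])
        assert overlap_proportion(q, far) == 0.0
        half = iset([("chr1", 50, 60), ("chr1", 250, 260)])
        assert overlap_proportion(q, half) == 0.5

    def test_empty_query(self):
        with pytest.raises(ValueError):
            overlap_proportion(IntervalSet(), iset([("chr1", 0, 10)]))


class TestFisherEnrichment:
    def universe(self, n):
        return iset([("chr1", i * 1000, i * 1000 + 100) for i in range(n)], "u")

    def test_small_table_exact_value(self):
        """[[2,0],[0,2]]: one-sided hypergeometric p = 1/6."""
        uni = self.universe(4)
        target = iset([("chr1", 0, 100), ("chr1", 1000, 1100)], "t")
        res = fisher_enrichment({"u0", "u1"}, {"T": target}, uni)
        assert res[0].pvalue == pytest.approx(1 / 6)
        assert res[0].support == 2

    def test_target_equals_universe_no_discrimination(self):
        uni = self.universe(6)
        res = fisher_enrichment({"u0", "u1"}, {"T": uni}, uni)
        assert res[0].pvalue == 1.0

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            fisher_enrichment({"zz"}, {"T": self.universe(3)}, self.universe(3))

    def test_matches_exhaustive_fixed_margin_enumeration(self, rng):
        """p equals direct enumeration over all tables with the observed
        margins, for universes up to 20 regions."""
        for _ in range(30):
            n = int(rng.integers(4, 21))
            n_query = int(rng.integers(1, n))
            n_target = int(rng.integers(1, n))
            query = {f"u{i}" for i in rng.choice(n, n_query, replace=False)}
            tidx = rng.choice(n, n_target, replace=False)
            uni = self.universe(n)
            target = iset([(uni[i].chrom, uni[i].start, uni[i].end) for i in tidx], "t")
            res = fisher_enrichment(query, {"T": target}, uni)
            a_obs = len(query & {f"u{i}" for i in tidx})
            # enumeration: choose which query regions hit the target
            total = comb(n, n_target)
            p_brute = sum(
                comb(n_query, a) * comb(n - n_query, n_target - a)
                for a in range(a_obs, min(n_query, n_target) + 1)
                if n_target - a <= n - n_query
            ) / total
            assert res[0].pvalue == pytest.approx(p_brute, rel=1e-9)


class TestBinomialEnrichment:
    def universe_query(self, n):
        return iset([("chr1", i * 1000, i * 1000 + 100) for i in range(n)], "q")

    def test_full_genome_annotation(self):
        q = self.universe_query(10)
        ann = iset([("chr1", 0, 100_000)], "a")
        res = binomial_enrichment(q, ann, genome_size=100_000)
        assert res.pvalue == 1.0 and res.effect == pytest.approx(1.0)

    def test_half_genome_all_hits(self):
        q = self.universe_query(10)  # regions within the first 10 kb
        ann = iset([("chr1", 0, 50_000)], "a")
        res = binomial_enrichment(q, ann, genome_size=100_000)
        assert res.pvalue == pytest.approx(2.0**-10)
        assert res.effect == pytest.approx(2.0)

    def test_no_hits_p_one(self):
        q = self.universe_query(5)
        ann = iset([("chr2", 0, 1000)], "a")
        res = binomial_enrichment(q, ann, genome_size=100_000)
        assert res.pvalue == 1.0 and res.support == 0

    def test_p_monotone_in_k(self):
        n, f = 12, 0.3
        ps = [float(stats.binom.sf(k - 1, n, f)) for k in range(n + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestGenomicContext:
    genes = [
        GeneModel("g1", "chr1", 50_000, "+", 50_000, 70_000,
                  exons=((50_000, 51_000), (60_000, 61_000), (69_000, 70_000))),
    ]

    def label(self, span):
        return annotate_genomic_context(iset([("chr1", *span)]), self.genes)[0]

    def test_priority_table(self):
        assert self.label((49_900, 50_100)) == "promoter"      # straddles TSS
        assert self.label((150_000, 150_200)) == "distal_intergenic"
        assert self.label((60_100, 60_300)) == "exonic"
        assert self.label((55_000, 55_200)) == "intronic"
        # intronic midpoint inside the promoter window: promoter wins
        assert self.label((52_000, 52_200)) == "promoter"

    def test_no_gene_models_warns(self):
        with pytest.warns(UserWarning):
            labels = annotate_genomic_context(iset([("chr1", 0, 100)]), [])
        assert labels == ["distal_intergenic"]


class TestRegulatoryDomains:
    sizes = {"chr1": 3_000_000}

    def test_basal_coordinates_plus_strand(self):
        genes = [GeneModel("g", "chr1", 100_000, "+", 100_000, 110_000)]
        bs, be, _, _ = regulatory_domains(genes, self.sizes)["g"]
        assert (bs, be) == (95_000, 101_000)

    def test_isolated_gene_extends_one_megabase(self):
        genes = [GeneModel("g", "chr1", 1_500_000, "+", 1_500_000, 1_510_000)]
        bs, be, es, ee = regulatory_domains(genes, self.sizes)["g"]
        assert es == bs - 1_000_000
        assert ee == be + 1_000_000

    def test_extension_stops_at_neighbor_basal(self):
        genes = [
            GeneModel("a", "chr1", 1_000_000, "+", 1_000_000, 1_010_000),
            GeneModel("b", "chr1", 1_200_000, "+", 1_200_000, 1_210_000),
        ]
        doms = regulatory_domains(genes, self.sizes)
        assert doms["a"][3] == doms["b"][0]  # a's right edge = b's basal start
        assert doms["b"][2] == doms["a"][1]  # b's left edge = a's basal end

    def test_region_between_distant_genes_assigned_to_near_one_only(self):
        genes = [
            GeneModel("near", "chr1", 200_000, "+", 200_000, 210_000),
            GeneModel("far", "chr1", 2_900_000, "+", 2_900_000, 2_910_000),
        ]
        regions = iset([("chr1", 1_100_000, 1_100_200)], "r")
        assoc = assign_regions_to_genes(regions, genes, self.sizes)
        assert assoc["r0"] == ["near"]

    def test_invariants(self, rng):
        genes = [
            GeneModel(f"g{i}", "chr1", int(t), "+" if i % 2 else "-", int(t), int(t) + 5000)
            for i, t in enumerate(np.sort(rng.integers(10_000, 2_900_000, 12)))
        ]
        doms = regulatory_domains(genes, self.sizes)
        for bs, be, es, ee in doms.values():
            assert es <= bs < be <= ee            # basal within extended
            assert bs - es <= 1_000_000
            assert ee - be <= 1_000_000
        regions = iset([("chr1", int(s), int(s) + 300)
                        for s in rng.integers(0, 2_900_000, 40)], "r")
        a1 = assign_regions_to_genes(regions, genes, self.sizes)
        a2 = assign_regions_to_genes(regions, genes[::-1], self.sizes)
        assert a1 == a2  # gene input order irrelevant


class TestWilcoxon:
    def test_small_sample_exact(self):
        res, _, _ = compare_lfc_distributions([1, 2], [3, 4])
        assert res.pvalue == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_identical_samples(self):
        res, _, _ = compare_lfc_distributions([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.pvalue == 1.0

    def test_exact_matches_full_permutation(self, rng):
        """Enumeration path equals a literal permutation oracle, n+m <= 12
        (ties included via midranks)."""
        for _ in range(20):
            n, m = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            vals = np.round(rng.normal(size=n + m), 1)  # rounding forces ties
            a, b = vals[:n], vals[n:]
            res, _, _ = compare_lfc_distributions(a, b)
            ranks = stats.rankdata(vals, method="average")
            mean_W = n * (n + m + 1) / 2
            obs = abs(ranks[:n].sum() - mean_W)
            count = total = 0
            for group_a in itertools.combinations(range(n + m), n):
                total += 1
                if abs(ranks[list(group_a)].sum() - mean_W) >= obs - 1e-9:
                    count += 1
            assert res.pvalue == pytest.approx(count / total, rel=1e-9)

    def test_normal_approximation_close_to_exact(self, rng):
        """At n = m = 30 (tie-free) the normal path tracks the exact
        distribution within 0.02 (independent library oracle)."""
        for _ in range(20):
            a = rng.normal(0, 1, 30)
            b = rng.normal(0.3, 1, 30)
            res, _, _ = compare_lfc_distributions(a, b)
            assert res.method == "normal"
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.pvalue == pytest.approx(ref.pvalue, abs=0.02)

    def test_meta_profile_filter(self):
        _, fa, fb = compare_lfc_distributions([0.2, 0.6, -0.7], [0.1, 0.4, 2.0])
        np.testing.assert_allclose(sorted(fa), [-0.7, 0.6])
        np.testing.assert_allclose(fb, [2.0])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_lfc_distributions([], [1.0, 2.0])


class TestAccessibilityCorrelation:
    def test_identical_vectors(self):
        r = accessibility_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.statistic == pytest.approx(1.0)

    def test_hand_computed_logged_values(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
        la, lb = np.log2(a + 1), np.log2(b + 1)
        expected = np.corrcoef(la, lb)[0, 1]
        res = accessibility_correlation(a, b)
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            accessibility_correlation([1, 1, 1], [1, 2, 3])


def test_known_motif_enrichment_on_planted_regions(small_sim):
    """Regions carrying the planted motif are enriched for it against
    motif-free regions; a motif absent everywhere reports no support."""
    from atacdyn.motifs import PWM, make_cdx_like_pwm
    from atacdyn.simulate import simulate_genome

    cfg, regions, truths = small_sim
    seqs = simulate_genome(truths, cfg)
    with_motif = IntervalSet(
        (t.interval for t in truths if t.motif is not None), label="fg"
    )
    without = IntervalSet(
        (t.interval for t in truths if t.motif is None), label="bg"
    )
    cdx = make_cdx_like_pwm()
    results = known_motif_enrichment(
        with_motif, without, [cdx], seqs, cfg.chrom_sizes()
    )
    assert results[0].enriched


def test_known_motif_enrichment_no_support():
    """A motif that never occurs reports p = 1 with zero support."""
    from atacdyn.motifs import PWM

    probs = np.full((4, 8), 0.01 / 3)
    probs[1] = 0.99  # strong all-C motif
    blank = PWM("allC", probs / probs.sum(axis=0, keepdims=True))
    seqs = {"chr1": "AGTA" * 500}  # C never occurs
    fg = iset([("chr1", 100, 400)], "f")
    bg = iset([("chr1", 800, 1100)], "b")
    results = known_motif_enrichment(fg, bg, [blank], seqs, {"chr1": 2000})
    assert results[0].pvalue == 1.0 and results[0].support == 0
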