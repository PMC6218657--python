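"""Peak calling, fragment counting, FPM tracks and IDR replicate combination."""

import numpy as np
import pandas as pd
import pytest

from atacdyn.idr import combine_replicates, estimate_idr, match_replicate_peaks
from atacdyn.peaks import (
    CountMatrix,
    PeakCall,
    SampleInfo,
    build_consensus_peaks,
    call_candidate_peaks,
    count_fragments,
    coverage_track_fpm,
    peaks_to_intervals,
)
from atacdyn.regions import GenomicInterval, IntervalSet
from atacdyn.simulate import simulate_idr_scores


def frags(rows, sample="S_r1"):
    return pd.DataFrame(
        [{"chrom": c, "start": s, "end": e, "sample": sample} for c, s, e in rows]
    )


class TestPeakCaller:
    def test_empty_input_warns_and_returns_nothing(self):
        with pytest.warns(UserWarning):
            assert call_candidate_peaks(frags([]), {"chr1": 10_000}) == []

    def test_uniform_background_rarely_calls(self, rng):
        """Uniform fragments: false windows stay below the Bonferroni bound
        (n_windows x p per seed), averaged over 20 seeds."""
        chrom_len = 500_000
        n_windows = (chrom_len - 300) // 100 + 1
        p = 1e-4
        total = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            starts = r.integers(0, chrom_len - 200, size=5_000)
            df = pd.DataFrame(
                {"chrom": "chr1", "start": starts, "end": starts + 150, "sample": "S_r1"}
            )
            total += len(call_candidate_peaks(df, {"chr1": chrom_len}, p_threshold=p))
        assert total <= 3 * 20 * n_windows * p  # 3x the expected bound

    def test_enriched_region_is_called(self, rng):
        """A region at 10x background density yields one covering peak."""
        chrom_len = 200_000
        bg = rng.integers(0, chrom_len - 200, size=2_000)
        peak = rng.integers(100_000, 100_400, size=400)
        starts = np.concatenate([bg, peak])
        df = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 120, "sample": "S_r1"}
        )
        calls = call_candidate_peaks(df, {"chr1": chrom_len}, p_threshold=1e-4)
        covering = [
            c for c in calls if c.interval.start <= 100_200 <= c.interval.end
        ]
        assert len(covering) == 1
        c = covering[0]
        assert c.score > 0
        assert 0 <= c.summit < len(c.interval)


class TestCounting:
    consensus = IntervalSet(
        [
            GenomicInterval("chr1", 100, 200, name="a"),
            GenomicInterval("chr1", 300, 400, name="b"),
        ]
    )

    def test_examples(self):
        df = frags(
            [("chr1", 120, 180), ("chr1", 0, 50), ("chr1", 150, 350)] * 1
        )
        cm = count_fragments(df, self.consensus)
        assert cm.counts[:, 0].tolist() == [2, 1]

    def test_fragment_spanning_two_regions_counts_in_both(self):
        df = frags([("chr1", 150, 350)] * 3)
        cm = count_fragments(df, self.consensus)
        assert cm.counts[:, 0].tolist() == [3, 3]

    def test_overlapping_consensus_rejected(self):
        bad = IntervalSet(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)]
        )
        with pytest.raises(ValueError, match="non-overlapping"):
            count_fragments(frags([("chr1", 0, 10)]), bad)

    def test_column_sum_bounded_by_fragments(self, small_sim):
        from atacdyn.simulate import simulate_fragments

        cfg, regions, truths = small_sim
        df = simulate_fragments(truths, cfg, "D4SC_r1")
        cm = count_fragments(df, regions)
        # spacing >= 500 and length <= 2000: a fragment can hit at most 4 regions
        assert cm.counts[:, 0].sum() <= 4 * len(df)


class TestCoverage:
    def test_fpm_values(self):
        df = frags([("chr1", 10, 20), ("chr1", 100, 110)])
        track = coverage_track_fpm(df, "S_r1", {"chr1": 200})
        assert track.values["chr1"][15] == pytest.approx(500_000.0)
        assert track.values["chr1"][50] == 0.0

    def test_fpm_scale_invariance(self):
        rows = [("chr1", 10, 20), ("chr1", 100, 110)]
        t1 = coverage_track_fpm(frags(rows), "S_r1", {"chr1": 200})
        t2 = coverage_track_fpm(frags(rows * 2), "S_r1", {"chr1": 200})
        np.testing.assert_allclose(t1.values["chr1"], t2.values["chr1"])

    def test_missing_sample_errors(self):
        with pytest.raises(ValueError, match="nope"):
            coverage_track_fpm(frags([("chr1", 0, 10)]), "nope", {"chr1": 100})


class TestConsensus:
    def test_single_condition_unchanged(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600)])
        cons = build_consensus_peaks([s])
        assert [(iv.start, iv.end) for iv in cons] == [(0, 100), (500, 600)]

    def test_merge_and_contributions(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)], label="A")
        b = IntervalSet([GenomicInterval("chr1", 50, 150)], label="B")
        c = IntervalSet([GenomicInterval("chr2", 0, 10)], label="C")
        cons, contribs = build_consensus_peaks([a, b, c], return_contributions=True)
        assert [(iv.chrom, iv.start, iv.end) for iv in cons] == [
            ("chr1", 0, 150),
            ("chr2", 0, 10),
        ]
        assert contribs == [("A", "B"), ("C",)]


def make_peaks(spans, scores, chrom="chr1"):
    return [
        PeakCall(GenomicInterval(chrom, s, e), score=float(sc), summit=(e - s) // 2)
        for (s, e), sc in zip(spans, scores)
    ]


class TestIdr:
    def test_input_validation(self):
        with pytest.raises(ValueError, match="50"):
            estimate_idr(np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError, match="constant"):
            estimate_idr(np.full(100, 1.0), np.arange(100.0))

    def test_identical_replicates_are_reproducible(self, rng):
        scores = rng.gamma(3, 2, size=500)
        res = estimate_idr(scores, scores)
        assert res.rho >= 0.95
        assert 0 < res.pi1 < 1
        top = np.argsort(scores)[-250:]
        assert (res.global_idr[top] < 0.1).all()

    def test_independent_scores_are_irreproducible(self):
        """Unrelated replicates: mean global IDR above 0.5 (20 seeds)."""
        means = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            res = estimate_idr(r.random(1000), r.random(1000))
            means.append(res.global_idr.mean())
        assert np.mean(means) > 0.5

    def test_local_idr_range_and_global_monotone(self, rng):
        s1, s2, _ = simulate_idr_scores(800, 0.6, 0.7, rng=rng)
        res = estimate_idr(s1, s2)
        assert ((res.local_idr >= 0) & (res.local_idr <= 1)).all()
        order = np.argsort(res.local_idr)
        assert (np.diff(res.global_idr[order]) >= -1e-12).all()
        assert res.global_idr[order][-1] <= 1.0


class TestCombineReplicates:
    def test_identical_calls_all_retained(self, rng):
        scores = rng.gamma(3, 2, size=500)
        spans = [(i * 1000, i * 1000 + 300) for i in range(500)]
        p1 = make_peaks(spans, scores)
        p2 = make_peaks(spans, scores)
        combined = combine_replicates(p1, p2, idr_threshold=0.1)
        assert len(combined) == 500

    def test_threshold_zero_empty(self, rng):
        scores = rng.gamma(3, 2, size=200)
        spans = [(i * 1000, i * 1000 + 300) for i in range(200)]
        out = combine_replicates(make_peaks(spans, scores), make_peaks(spans, scores),
                                 idr_threshold=0.0)
        assert len(out) == 0

    def test_disjoint_calls_empty_with_warning(self):
        p1 = make_peaks([(0, 100)], [5.0])
        p2 = make_peaks([(5000, 5100)], [5.0])
        with pytest.warns(UserWarning, match="no matched"):
            assert len(combine_replicates(p1, p2)) == 0

    def test_reciprocal_best_matching(self):
        p1 = make_peaks([(0, 100), (90, 250)], [1.0, 2.0])
        p2 = make_peaks([(80, 260)], [2.0])
        # p2[0] overlaps both; its best partner is p1[1] (160 bp vs 20 bp)
        assert match_replicate_peaks(p1, p2) == [(1, 0)]

    def test_pass_rates_planted_vs_noise_pairs(self):
        """Matched pairs with correlated (reproducible) scores pass
        IDR <= 0.1 at rate >= 0.9; matched pairs with independent noise
        scores pass at rate <= 0.2 (20-seed average)."""
        planted_rates, noise_rates = [], []
        for seed in range(20):
            s1, s2, lab = simulate_idr_scores(
                1000, 0.6, 0.8, rng=np.random.default_rng(seed)
            )
            res = estimate_idr(s1, s2)
            passed = res.global_idr <= 0.1
            planted_rates.append(passed[lab == 1].mean())
            noise_rates.append(passed[lab == 0].mean())
        assert np.mean(planted_rates) >= 0.9
        assert np.mean(noise_rates) <= 0.2

    def test_replicate_combination_on_simulated_fragments(self):
        """Fragment-level integration: the reproducible set contains no
        false peaks and covers most planted regions."""
        from atacdyn.simulate import SimConfig, default_samples, simulate_fragments, simulate_regions
        from atacdyn.peaks import call_candidate_peaks
        from atacdyn.regions import find_overlaps

        cfg = SimConfig(seed=21, regions_per_class=15, chromosomes=(("chr1", 1_000_000),),
                        samples=default_samples(2), baseline_mean=80.0,
                        background_fraction=0.3)
        regions, truths = simulate_regions(cfg)
        calls = {}
        for rep in (1, 2):
            df = simulate_fragments(truths, cfg, f"D5SC_r{rep}")
            calls[rep] = call_candidate_peaks(df, cfg.chrom_sizes())
        combined = combine_replicates(calls[1], calls[2], idr_threshold=0.1)
        assert len(combined) > 0
        # every reproducible peak sits on a planted region ...
        on_truth = {qi for qi, _ in find_overlaps(combined, regions)}
        assert len(on_truth) == len(combined)
        # ... and the majority of planted regions survive the gate (the
        # model always sacrifices the weakest tail of a pure-signal list)
        hit_regions = {qi for qi, _ in find_overlaps(regions, combined)}
        assert len(hit_regions) >= 0.5 * len(regions)
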