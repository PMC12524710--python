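import math

import numpy as np
import pytest

from peakrepro.consensus import build_consensus
from peakrepro.intervals_io import GenomicInterval, PeakSet, overlaps
from peakrepro.strategies import (
    StrategyConfig,
    default_thresholds,
    fisher_combine_pvalues,
    mspc_like,
    occurring_at_least_once,
    pairwise_union,
    rank_discordance_scorer,
    rank_product,
    replicate_rank_matrix,
    shared_by_all,
    threshold_sweep,
)

from _oracles import fisher_closed_form_m2, rank_product_pvalue_enum


def gi(c, s, e, p=None):
    return GenomicInterval(c, s, e, pvalue=p)


class TestBaselines:
    def test_at_least_once_returns_all_regions(self, toy_consensus):
        assert len(occurring_at_least_once(toy_consensus)) == 3

    def test_shared_by_all_toy(self, toy_consensus):
        res = shared_by_all(toy_consensus)
        assert [e.interval.key for e in res.entries] == [("chr1", 100, 250)]

    def test_disjoint_replicates_shared_by_all_empty(self):
        reps = [PeakSet("a", [gi("chr1", 0, 100, 1e-5)]),
                PeakSet("b", [gi("chr1", 500, 600, 1e-5)])]
        assert len(shared_by_all(build_consensus(reps))) == 0

    def test_single_replicate_extremes_coincide(self):
        cs = build_consensus([PeakSet("a", [gi("chr1", 0, 100, 1e-5)])])
        assert (occurring_at_least_once(cs).intervals
                == shared_by_all(cs).intervals)

    def test_identical_replicates_extremes_coincide(self):
        peaks = [gi("chr1", 0, 100, 1e-5), gi("chr1", 300, 350, 1e-6)]
        cs = build_consensus([PeakSet(f"r{i}", list(peaks)) for i in range(3)])
        assert (occurring_at_least_once(cs).intervals
                == shared_by_all(cs).intervals)


class TestFisher:
    def test_two_values_closed_form_examples(self):
        assert fisher_combine_pvalues([0.01, 0.01]) == pytest.approx(
            1.021e-3, rel=1e-3
        )
        assert fisher_combine_pvalues([1e-6, 1e-6]) == pytest.approx(
            2.86e-11, rel=1e-2
        )

    def test_singleton_identity(self):
        for p in (1e-12, 0.035, 1.0):
            assert fisher_combine_pvalues([p]) == p

    def test_matches_closed_form_on_grid(self):
        # df=4 upper tail: e^(−x/2)(1+x/2)
        grid = np.logspace(-10, 0, 100)
        for p1, p2 in zip(grid, grid[::-1]):
            expected = fisher_closed_form_m2(p1, p2)
            assert fisher_combine_pvalues([p1, p2]) == pytest.approx(
                expected, rel=1e-12
            )

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [1.2], []):
            with pytest.raises(ValueError):
                fisher_combine_pvalues(bad)


class TestMspcLike:
    def test_toy_ranking(self, toy_consensus):
        res = mspc_like(toy_consensus)
        assert res.entries[0].interval.key == ("chr1", 100, 250)
        assert res.entries[0].score == pytest.approx(2.86e-11, rel=1e-2)
        assert res.entries[0].rank == 1

    def test_weak_single_member_retained(self, toy_consensus):
        # chr1:300-400 has a single member p=1e-5 < weak threshold
        res = mspc_like(toy_consensus)
        keys = [e.interval.key for e in res.entries]
        assert ("chr1", 300, 400) in keys
        score = next(e.score for e in res.entries
                     if e.interval.key == ("chr1", 300, 400))
        assert score == 1e-5  # m=1 Fisher identity

    def test_noise_class_excluded(self, toy_consensus):
        # chr1:500-600's only member p=0.5 exceeds the weak threshold
        keys = [e.interval.key for e in mspc_like(toy_consensus).entries]
        assert ("chr1", 500, 600) not in keys

    def test_support_filter(self, toy_consensus):
        cfg = StrategyConfig(min_overlap_replicates=2)
        assert len(mspc_like(toy_consensus, cfg)) == 1

    def test_missing_pvalue_names_region_and_replicate(self):
        reps = [PeakSet("repA", [gi("chr1", 0, 100)]),
                PeakSet("repB", [gi("chr1", 50, 150, 1e-5)])]
        with pytest.raises(ValueError, match="repA"):
            mspc_like(build_consensus(reps))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            StrategyConfig(stringency_threshold=1e-3, weak_threshold=1e-4)


class TestRankProduct:
    def _consensus(self, pvals_by_rep):
        """Build disjoint one-peak-per-region replicates from a dict
        rep_id -> {region_index: pvalue} over regions at 1000*i."""
        m = max(max(d) for d in pvals_by_rep.values()) + 1
        reps = []
        for rep_id, d in pvals_by_rep.items():
            peaks = [gi("chr1", 1000 * j, 1000 * j + 100, p) for j, p in d.items()]
            reps.append(PeakSet(rep_id, peaks))
        cs = build_consensus(reps)
        assert len(cs) == m
        return cs

    def test_top_region_pvalue_is_one_ninth(self):
        # M=3, N=2, one region ranked (1,1): P(RP<=1) = (1/3)^2
        cs = self._consensus({
            "a": {0: 1e-8, 1: 1e-5, 2: 1e-4},
            "b": {0: 1e-7, 1: 1e-4, 2: 1e-5},
        })
        res = rank_product(cs)
        top = next(e for e in res.entries if e.interval.start == 0)
        assert top.score == pytest.approx(1 / 9)

    def test_absent_replicate_gets_worst_rank(self):
        cs = self._consensus({
            "a": {0: 1e-8, 1: 1e-5, 2: 1e-4, 3: 1e-6},
            "b": {0: 1e-7, 1: 1e-4, 2: 1e-5},
        })
        ranks = replicate_rank_matrix(cs)
        assert ranks[3, 1] == 4.0  # region 3 missing from rep b, M=4

    def test_identical_replicates_preserve_pvalue_order(self):
        ps = {0: 1e-8, 1: 1e-4, 2: 1e-6}
        cs = self._consensus({"a": dict(ps), "b": dict(ps), "c": dict(ps)})
        res = rank_product(cs)
        order = [e.interval.start // 1000 for e in res.entries]
        assert order == [0, 2, 1]

    def test_needs_two_replicates(self):
        cs = build_consensus([PeakSet("a", [gi("chr1", 0, 100, 1e-5)])])
        with pytest.raises(ValueError):
            rank_product(cs)

    def test_matches_exhaustive_enumeration_small(self):
        """p-values equal exhaustive enumeration for M<=5, N<=3."""
        rng = np.random.default_rng(99)
        for m in range(2, 6):
            for n in (2, 3):
                pvals_by_rep = {}
                for i in range(n):
                    # random subset of regions present in this replicate,
                    # region 0 always present so M is stable
                    present = {0} | {
                        j for j in range(1, m) if rng.random() < 0.7
                    }
                    pvals_by_rep[f"r{i}"] = {
                        j: float(rng.uniform(1e-8, 1e-4)) for j in present
                    }
                all_regions = set().union(*pvals_by_rep.values())
                if len(all_regions) != m:
                    for j in range(m):
                        pvals_by_rep["r0"].setdefault(
                            j, float(rng.uniform(1e-8, 1e-4))
                        )
                cs = self._consensus(pvals_by_rep)
                ranks = replicate_rank_matrix(cs)
                res = rank_product(cs)
                rp_by_region = dict(
                    zip([int(r.interval.start // 1000) for r in cs.regions],
                        ranks.prod(axis=1))
                )
                for e in res.entries:
                    region_idx = int(e.interval.start // 1000)
                    expected = rank_product_pvalue_enum(
                        rp_by_region[region_idx], m, n
                    )
                    assert e.score == pytest.approx(expected, abs=0), (m, n)


class TestPairwiseUnion:
    def test_two_replicates_single_pair(self):
        a = PeakSet("a", [gi("chr1", 0, 100, 1e-8), gi("chr1", 500, 600, 1e-5)])
        b = PeakSet("b", [gi("chr1", 50, 150, 1e-7), gi("chr1", 900, 950, 1e-4)])
        res = pairwise_union([a, b], threshold=1.0)
        # only the intersecting pair survives, merged into one interval
        assert [e.interval.key for e in res.entries] == [("chr1", 0, 150)]
        assert res.entries[0].score == 0.0  # both ranked 1 in their replicate

    def test_threshold_one_equals_all_intersecting_pairs(self):
        rng = np.random.default_rng(5)
        reps = []
        for i in range(3):
            peaks = [
                gi("chr1", int(s), int(s) + 80, float(rng.uniform(1e-8, 1e-4)))
                for s in rng.choice(np.arange(0, 5000, 100), 15, replace=False)
            ]
            reps.append(PeakSet(f"r{i}", peaks))
        res = pairwise_union(reps, threshold=1.0)
        # brute force: every peak intersecting a peak of another replicate
        expected_peaks = set()
        for ra in reps:
            for rb in reps:
                if ra.replicate_id == rb.replicate_id:
                    continue
                for pa in ra.peaks:
                    if any(overlaps(pa, pb) for pb in rb.peaks):
                        expected_peaks.add(pa.key)
        from peakrepro.intervals_io import merge_intervals

        expected = merge_intervals(
            [GenomicInterval(*k) for k in expected_peaks]
        )
        assert sorted(e.interval.key for e in res.entries) == sorted(
            iv.key for iv in expected
        )

    def test_only_concordant_pair_passes(self):
        # A and B rank their shared peak identically (score 0); C's peak
        # intersects A's second peak with maximal discordance
        a = PeakSet("a", [gi("chr1", 0, 100, 1e-8), gi("chr1", 500, 600, 1e-4)])
        b = PeakSet("b", [gi("chr1", 50, 150, 1e-8), gi("chr1", 900, 950, 1e-4)])
        c = PeakSet("c", [gi("chr1", 550, 650, 1e-9), gi("chr1", 2000, 2100, 1e-4)])
        res = pairwise_union([a, b, c], threshold=0.25)
        # surviving: a1+b1 (score 0); a2 (rank 2) vs c1 (rank 1) has
        # discordance 1/2 > 0.25, so the A∩C pair is filtered
        assert [e.interval.key for e in res.entries] == [("chr1", 0, 150)]

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            pairwise_union([PeakSet("a", [gi("chr1", 0, 100, 1e-5)])])

    def test_scorer_range(self):
        s = rank_discordance_scorer(
            gi("chr1", 0, 10), gi("chr1", 5, 15), 1.0, 10.0, 10, 10
        )
        assert s == pytest.approx(0.9)


class TestThresholdSweep:
    def test_direct_filter(self):
        from peakrepro.strategies import RankedEntry, RankedResult

        entries = [
            RankedEntry(gi("chr1", 0, 10), 0.2, 1),
            RankedEntry(gi("chr1", 20, 30), 0.6, 2),
        ]
        res = RankedResult("x", entries, smaller_is_better=True)
        sets = threshold_sweep(res, [0.25, 0.75])
        assert [len(s) for s in sets] == [1, 2]
        # loosest includes everything; impossible threshold excludes all
        assert len(threshold_sweep(res, [1.0])[0]) == 2
        assert threshold_sweep(res, [0.1])[0] == []

    def test_nestedness_on_real_result(self, rep6_bundle):
        cs = build_consensus(rep6_bundle.replicates)
        res = mspc_like(cs)
        ts = default_thresholds(res, n=10)
        sets = threshold_sweep(res, ts)
        for strict, loose in zip(sets, sets[1:]):
            strict_keys = {iv.key for iv in strict}
            assert strict_keys <= {iv.key for iv in loose}
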