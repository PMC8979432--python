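"""Loop-set matching, colocalization and replicate correlation."""

import math

import numpy as np
import pytest

from hicut.benchmark import (
    colocalization,
    coverage_vector,
    match_loops,
    match_loops_to_loops,
    spearman_correlation,
)
from hicut.io import GenomicInterval, LoopRecord, ValidPair
from hicut.pairs import Interaction

from oracles import oracle_colocalization, oracle_match_loops, random_instance


def loop(c, s1, e1, s2, e2):
    return LoopRecord(GenomicInterval(c, s1, e1), GenomicInterval(c, s2, e2))


class TestMatchLoops:
    REF = [loop("chr1", 10_000, 15_000, 60_000, 65_000)]

    def test_containment_match(self):
        rep = match_loops(self.REF, [Interaction("chr1", 12_000, 61_000)])
        assert (rep.n_matched, rep.fraction_matched) == (1, 1.0)

    def test_slack_rescues_a_near_miss(self):
        near = [Interaction("chr1", 12_000, 59_000)]
        assert match_loops(self.REF, near, slack=0).n_matched == 0
        assert match_loops(self.REF, near, slack=2_000).n_matched == 1

    def test_both_anchors_must_be_spanned_by_one_interaction(self):
        two_halves = [
            Interaction("chr1", 12_000, 200_000),   # hits anchorA only
            Interaction("chr1", 1_000, 61_000),     # hits anchorB only
        ]
        assert match_loops(self.REF, two_halves).n_matched == 0

    def test_planted_52_percent_fixture(self):
        rng = np.random.default_rng(1)
        loops, hits = [], []
        for k in range(100):
            sA = 1_000_000 * k
            lp = loop("chr1", sA, sA + 5_000, sA + 500_000, sA + 505_000)
            loops.append(lp)
            if k < 52:
                hits.append(
                    Interaction("chr1", sA + 2_500, sA + 502_500)
                )
        decoys = [
            Interaction("chr1", int(p), int(p) + 30_000)
            for p in rng.integers(100_000_000, 150_000_000, size=50)
        ]
        rep = match_loops(loops, hits + decoys)
        assert rep.fraction_matched == pytest.approx(0.52)
        assert rep.n_matched == oracle_match_loops(loops, hits + decoys)

    def test_empty_reference_is_an_error(self):
        with pytest.raises(ValueError):
            match_loops([], [Interaction("chr1", 1, 50_000)])

    def test_slack_monotonicity_on_random_instances(self):
        for seed in range(5):
            _, _, loops, _, _ = random_instance(seed)
            rng = np.random.default_rng(seed)
            inter = [
                Interaction("chr1", int(a), int(a) + int(rng.integers(5_000, 60_000)))
                for a in rng.integers(1, 150_000, size=30)
            ]
            fracs = [
                match_loops(loops, inter, slack=s).fraction_matched
                for s in (0, 500, 2_000, 10_000)
            ]
            assert fracs == sorted(fracs)


class TestMatchLoopsToLoops:
    def test_identical_sets_fully_match(self):
        loops = [loop("chr1", 0, 1_000, 50_000, 51_000),
                 loop("chr2", 0, 1_000, 90_000, 91_000)]
        assert match_loops_to_loops(loops, loops).fraction_matched == 1.0

    def test_disjoint_chromosomes_no_match(self):
        a = [loop("chr1", 0, 1_000, 50_000, 51_000)]
        b = [loop("chr2", 0, 1_000, 50_000, 51_000)]
        assert match_loops_to_loops(a, b).fraction_matched == 0.0

    def test_hand_built_8_of_20(self):
        ref = [loop("chr1", 100_000 * k, 100_000 * k + 2_000,
                    100_000 * k + 50_000, 100_000 * k + 52_000) for k in range(20)]
        query = [loop("chr1", 100_000 * k + 1_000, 100_000 * k + 3_000,
                      100_000 * k + 51_000, 100_000 * k + 53_000) for k in range(8)]
        rep = match_loops_to_loops(ref, query)
        assert rep.fraction_matched == pytest.approx(0.40)

    def test_one_bp_overlap_suffices(self):
        ref = [loop("chr1", 100, 200, 5_000, 5_100)]
        query = [loop("chr1", 199, 300, 5_099, 5_200)]
        assert match_loops_to_loops(ref, query).n_matched == 1
        query_apart = [loop("chr1", 200, 300, 5_100, 5_200)]
        assert match_loops_to_loops(ref, query_apart).n_matched == 0


class TestColocalization:
    def test_all_anchors_in_peaks(self):
        inter = [Interaction("chr1", 150, 50_150)]
        peaks = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 50_100, 50_200)]
        assert colocalization(inter, peaks, "any_anchor") == 1.0
        assert colocalization(inter, peaks, "both_anchors") == 1.0

    def test_half_hit_via_anchor1_only(self):
        inter = [Interaction("chr1", 150, 900_000), Interaction("chr1", 700_000, 950_000)]
        peaks = [GenomicInterval("chr1", 100, 200)]
        assert colocalization(inter, peaks, "any_anchor") == 0.5
        assert colocalization(inter, peaks, "both_anchors") == 0.0

    def test_modes_ordered_and_match_oracle_on_random_instances(self):
        for seed in range(8):
            pairs, peaks, _, _, p = random_instance(seed)
            if not peaks:
                continue
            inter = [
                Interaction(q.chrom1, q.pos1, q.pos2)
                for q in pairs
                if q.chrom1 == q.chrom2 and q.pos1 < q.pos2
            ]
            if not inter:
                continue
            any_f = colocalization(inter, peaks, "any_anchor")
            both_f = colocalization(inter, peaks, "both_anchors")
            assert both_f <= any_f
            assert any_f == pytest.approx(oracle_colocalization(inter, peaks, "any_anchor"))
            assert both_f == pytest.approx(oracle_colocalization(inter, peaks, "both_anchors"))

    def test_empty_interactions_error(self):
        with pytest.raises(ValueError):
            colocalization([], [GenomicInterval("chr1", 0, 100)], "any_anchor")


class TestCoverageVector:
    def test_both_ends_binned(self):
        cv = coverage_vector(
            [ValidPair("R", "chr1", 1_000, "+", "chr1", 51_000, "-")], 10_000
        )
        assert cv.counts["chr1"][0] == 1 and cv.counts["chr1"][5] == 1

    def test_bin_boundary_uses_one_based_floor(self):
        cv = coverage_vector(
            [ValidPair("R", "chr1", 10_000, "+", "chr1", 10_001, "-")], 10_000
        )
        # pos 10,000 is the last base of bin 0; pos 10,001 opens bin 1
        assert cv.counts["chr1"][0] == 1 and cv.counts["chr1"][1] == 1

    def test_total_counts_two_per_cis_pair(self):
        pairs = [
            ValidPair(f"R{k}", "chr1", 1 + k, "+", "chr1", 90_000 + k, "-")
            for k in range(7)
        ] + [ValidPair("T", "chr1", 5, "+", "chr2", 5, "-")]
        assert coverage_vector(pairs, 10_000).total == 14

    def test_empty_input(self):
        assert coverage_vector([], 10_000).total == 0


class TestSpearman:
    def _cv(self, counts):
        from hicut.benchmark import CoverageVector

        return CoverageVector(bin_size=10_000, counts={"chr1": np.asarray(counts)})

    def test_self_correlation_is_one(self):
        a = self._cv([3, 1, 4, 1, 5, 9, 2, 6])
        assert spearman_correlation(a, a) == pytest.approx(1.0)

    def test_antitone_is_minus_one(self):
        a = self._cv([1, 2, 3, 4, 5])
        b = self._cv([10, 8, 6, 4, 2])
        assert spearman_correlation(a, b) == pytest.approx(-1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(20, size=400)
        a, b = self._cv(x), self._cv(rng.poisson(20, size=400))
        rho = spearman_correlation(a, b)
        a_t = self._cv(np.exp(x / 10.0))
        assert spearman_correlation(a_t, b) == pytest.approx(rho, abs=1e-12)

    def test_constant_vector_gives_nan_sentinel(self):
        a = self._cv([5, 5, 5, 5])
        b = self._cv([1, 2, 3, 4])
        assert math.isnan(spearman_correlation(a, b))

    def test_mismatched_bin_sizes_rejected(self):
        from hicut.benchmark import CoverageVector

        a = CoverageVector(10_000, {"chr1": np.array([1, 2])})
        b = CoverageVector(5_000, {"chr1": np.array([1, 2])})
        with pytest.raises(ValueError):
            spearman_correlation(a, b)
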