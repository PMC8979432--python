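"""Contact binning, Knight-Ruiz balancing and APA aggregation."""

import numpy as np
import pytest
import scipy.sparse as sp

from hicut.apa import (
    BalanceError,
    ContactMatrix,
    LociPair,
    aggregate,
    bin_pairs,
    enumerate_loci,
    kr_balance,
    random_loci,
    sample_loci,
)
from hicut.io import GenomicInterval, ValidPair
from hicut.pairs import AnalysisParams

from oracles import oracle_aggregate


def vp(read_id, c, p1, p2):
    return ValidPair(read_id, c, p1, "+", c, p2, "-")


class TestBinPairs:
    def test_adjacent_bins(self):
        mats = bin_pairs([vp("R", "chr1", 1, 5_001)], 5_000)
        assert mats["chr1"].matrix[0, 1] == 1 and mats["chr1"].matrix[1, 0] == 1

    def test_within_bin_pair_hits_diagonal(self):
        mats = bin_pairs([vp("R", "chr1", 15_001, 19_999)], 5_000)
        assert mats["chr1"].matrix[3, 3] == 1

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        pairs = [
            vp(f"R{k}", "chr1", int(a), int(a) + int(d))
            for k, (a, d) in enumerate(
                zip(rng.integers(1, 800_000, 1_000), rng.integers(1, 200_000, 1_000))
            )
        ]
        mats = bin_pairs(pairs, 5_000)
        assert mats["chr1"].mass == 1_000

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError):
            bin_pairs([], 0)


class TestKRBalance:
    def test_two_by_two_closed_form(self):
        w = kr_balance(np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert w == pytest.approx([1 / np.sqrt(2)] * 2)

    def test_doubly_stochastic_fixed_point(self):
        A = np.array([[0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]])
        assert kr_balance(A) == pytest.approx([1.0, 1.0, 1.0], abs=1e-5)

    def test_random_20x20_row_sums_within_tolerance(self):
        rng = np.random.default_rng(1)
        M = rng.random((20, 20))
        A = M + M.T
        w = kr_balance(A, tol=1e-6)
        rows = (A * np.outer(w, w)).sum(axis=1)
        assert np.abs(rows - 1).max() < 1e-6

    def test_empty_rows_excluded_with_nan_weights(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 3.0
        w = kr_balance(A)
        assert np.isnan(w[2]) and np.isnan(w[3])
        assert w[0] * 3.0 * w[1] == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        M = rng.random((15, 15)) + 0.1
        A = M + M.T
        perm = rng.permutation(15)
        w = kr_balance(A)
        w_p = kr_balance(A[np.ix_(perm, perm)])
        assert w_p == pytest.approx(w[perm], rel=1e-4)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            kr_balance(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_all_zero_matrix_is_an_error(self):
        with pytest.raises(BalanceError):
            kr_balance(np.zeros((3, 3)))


class TestEnumerateLoci:
    PARAMS = AnalysisParams()

    def _peaks(self, mids, width=400):
        return [
            GenomicInterval("chr1", m - width // 2, m + width // 2) for m in mids
        ]

    def test_below_min_separation_excluded(self):
        loci = enumerate_loci(self._peaks([10_000, 14_000]), 1_000, self.PARAMS)
        assert loci == []

    def test_exactly_max_separation_excluded(self):
        loci = enumerate_loci(self._peaks([10_000, 1_010_000]), 1_000, self.PARAMS)
        assert loci == []
        loci = enumerate_loci(self._peaks([10_000, 1_009_999]), 1_000, self.PARAMS)
        assert len(loci) == 1

    def test_all_pairs_of_five_mutually_in_range(self):
        mids = [100_000, 200_000, 300_000, 400_000, 500_000]
        loci = enumerate_loci(self._peaks(mids), 5_000, self.PARAMS)
        assert len(loci) == 10  # C(5, 2)

    def test_bin_level_deduplication(self):
        # two peaks in the same bin paired against a common partner
        peaks = self._peaks([100_000, 101_000, 400_000])
        loci = enumerate_loci(peaks, 5_000, self.PARAMS)
        # (100k,400k) and (101k,400k) collapse to one bin pair; (100k,101k) < 5 kb
        assert loci == [LociPair("chr1", 20, 80)]


class TestSampleLoci:
    LOCI = [LociPair("chr1", i, i + 30) for i in range(50)]

    def test_clamps_to_population(self):
        assert len(sample_loci(self.LOCI, 200_000, seed=0)) == 50

    def test_same_seed_reproducible(self):
        assert sample_loci(self.LOCI, 10, seed=5) == sample_loci(self.LOCI, 10, seed=5)

    def test_different_seeds_differ(self):
        big = [LociPair("chr1", i, i + 30) for i in range(10_000)]
        assert sample_loci(big, 100, seed=1) != sample_loci(big, 100, seed=2)


class TestAggregate:
    def _matrix_from_dense(self, D):
        return {
            "chr1": ContactMatrix(
                chrom="chr1", resolution=5_000, n_bins=D.shape[0],
                matrix=sp.csr_matrix(D),
            )
        }

    def test_single_locus_lone_center_pixel(self):
        n = 80
        D = np.zeros((n, n))
        D[30, 60] = D[60, 30] = 7.0
        mats = self._matrix_from_dense(D)
        res = aggregate(mats, [LociPair("chr1", 30, 60)], balanced=False)
        assert res.matrix[10, 10] == 7.0
        assert np.nansum(res.matrix) == 7.0
        assert res.n_pairs_used == 1

    def test_constant_matrix_scores_one(self):
        n = 90
        D = np.ones((n, n))
        mats = self._matrix_from_dense(D)
        res = aggregate(mats, [LociPair("chr1", 25, 60)], balanced=False)
        assert res.score == pytest.approx(1.0)

    def test_edge_and_near_diagonal_loci_dropped(self):
        n = 60
        mats = self._matrix_from_dense(np.ones((n, n)))
        loci = [
            LociPair("chr1", 5, 40),    # window exceeds left edge
            LociPair("chr1", 20, 55),   # window exceeds right edge
            LociPair("chr1", 20, 38),   # separation 18 <= 2w
            LociPair("chr1", 15, 45),   # usable
        ]
        res = aggregate(mats, loci, balanced=False)
        assert res.n_pairs_used == 1
        with pytest.raises(ValueError):
            aggregate(mats, loci[:3], balanced=False)

    def test_matches_naive_oracle_on_random_sparse_matrix(self):
        rng = np.random.default_rng(7)
        n = 120
        M = sp.random(n, n, density=0.05, random_state=3, data_rvs=lambda k: rng.integers(1, 6, k))
        A = (M + M.T).tocsr()
        cm = ContactMatrix(chrom="chr1", resolution=5_000, n_bins=n, matrix=A)
        kr_balance(cm)
        loci = [
            LociPair("chr1", int(i), int(i) + int(s))
            for i, s in zip(rng.integers(0, n, 60), rng.integers(21, 60, 60))
            if int(i) + int(s) < n
        ]
        res = aggregate({"chr1": cm}, loci)
        D = cm.balanced_dense()
        mean, score, n_used = oracle_aggregate(
            {"chr1": D}, {"chr1": n}, loci, w=10, corner=6
        )
        assert res.n_pairs_used == n_used
        np.testing.assert_allclose(res.matrix, mean, equal_nan=True)
        assert res.score == pytest.approx(score, nan_ok=True)

    def test_iid_noise_score_concentrates_at_one(self):
        rng = np.random.default_rng(11)
        n = 400
        M = rng.poisson(5.0, size=(n, n)).astype(float)
        A = np.triu(M) + np.triu(M, 1).T
        mats = self._matrix_from_dense(A)
        loci = [
            LociPair("chr1", int(i), int(i) + int(s))
            for i, s in zip(rng.integers(11, n - 80, 600), rng.integers(21, 70, 600))
        ]
        res = aggregate(mats, loci, balanced=False)
        assert res.score == pytest.approx(1.0, abs=0.1)


class TestRandomLoci:
    def test_respects_separation_range_and_count(self):
        params = AnalysisParams()
        loci = random_loci({"chr1": 2_000, "chr2": 2_000}, 500, params, 5_000, seed=4)
        assert len(loci) == 500
        for lp in loci:
            assert 1 <= lp.bin_j - lp.bin_i < 200
            assert 0 <= lp.bin_i and lp.bin_j < 2_000
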