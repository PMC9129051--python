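"""Mean-squared-residue machinery and greedy bicluster extraction."""

import itertools

import numpy as np
import pytest

from kneephen.biclustering import (
    Bicluster,
    anova_r2,
    find_bicluster,
    find_exclusive_biclusters,
    msr,
    multiple_node_deletion,
    node_addition,
    single_node_deletion,
)


def msr_oracle(matrix, rows, cols):
    """Direct double-loop evaluation of the residue formula."""
    sub = matrix[np.ix_(sorted(rows), sorted(cols))]
    m, n = sub.shape
    aiJ = sub.mean(axis=1)
    aIj = sub.mean(axis=0)
    aIJ = sub.mean()
    total = 0.0
    for i in range(m):
        for j in range(n):
            total += (sub[i, j] - aiJ[i] - aIj[j] + aIJ) ** 2
    return total / (m * n)


class TestMsr:
    def test_additive_matrix_has_zero_residue(self):
        h, _, _ = msr(np.array([[1.0, 2.0], [3.0, 4.0]]), [0, 1], [0, 1])
        assert h == pytest.approx(0.0, abs=1e-14)

    def test_checkerboard_hand_value(self):
        h, d_row, d_col = msr(np.array([[1.0, 0.0], [0.0, 1.0]]), [0, 1], [0, 1])
        assert h == pytest.approx(0.25)
        assert d_row == pytest.approx([0.25, 0.25])
        assert d_col == pytest.approx([0.25, 0.25])

    def test_constant_matrix(self):
        h, _, _ = msr(np.full((3, 4), 7.0), range(3), range(4))
        assert h == 0.0

    def test_h_is_mean_of_row_scores(self, rng):
        X = rng.standard_normal((8, 6))
        h, d_row, d_col = msr(X, range(8), range(6))
        assert h == pytest.approx(d_row.mean(), abs=1e-12)
        assert h == pytest.approx(d_col.mean(), abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_matrices(self, rng):
        for _ in range(200):
            m = int(rng.integers(2, 7))
            n = int(rng.integers(2, 6))
            X = rng.standard_normal((m, n))
            rows = sorted(rng.choice(m, size=int(rng.integers(2, m + 1)), replace=False))
            cols = sorted(rng.choice(n, size=int(rng.integers(2, n + 1)), replace=False))
            h, _, _ = msr(X, rows, cols)
            assert abs(h - msr_oracle(X, rows, cols)) < 1e-12

    def test_empty_index_error(self):
        with pytest.raises(ValueError):
            msr(np.eye(3), [], [0, 1])

    def test_shift_invariance(self, rng):
        X = rng.standard_normal((10, 8))
        h1, _, _ = msr(X, range(10), range(8))
        h2, _, _ = msr(X + 13.7, range(10), range(8))
        assert h1 == pytest.approx(h2, abs=1e-10)


class TestAnovaR2:
    def test_additive_submatrix_is_one(self):
        X = np.add.outer(np.arange(4.0), np.arange(3.0))
        assert anova_r2(X, range(4), range(3)) == pytest.approx(1.0)

    def test_checkerboard_is_zero(self):
        assert anova_r2(np.array([[1.0, 0.0], [0.0, 1.0]]), [0, 1], [0, 1]) == 0.0

    def test_constant_submatrix_error(self):
        with pytest.raises(ValueError, match="constant"):
            anova_r2(np.full((3, 3), 2.0), range(3), range(3))

    def test_pure_noise_expectation(self, rng):
        # two-way ANOVA on m x n iid noise explains (m+n-1)/(m*n) of variance
        m, n = 50, 10
        vals = [anova_r2(rng.standard_normal((m, n)), range(m), range(n)) for _ in range(200)]
        expected = (m + n - 1) / (m * n)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se + 1e-3


class TestSingleNodeDeletion:
    def test_converges_to_additive_rows(self):
        X = np.array([[1.0, 2.0], [2.0, 3.0], [0.0, 9.0]])
        rows, cols, conv = single_node_deletion(X, range(3), range(2), delta=1e-6)
        assert conv
        # exhaustive check: rows {0,1} over both columns is the maximal
        # zero-residue submatrix of this matrix
        assert set(rows) == {0, 1} and set(cols) == {0, 1}
        assert msr(X, rows, cols)[0] == pytest.approx(0.0, abs=1e-12)

    def test_no_op_when_already_below_delta(self, rng):
        X = rng.standard_normal((5, 4))
        h0, _, _ = msr(X, range(5), range(4))
        rows, cols, conv = single_node_deletion(X, range(5), range(4), delta=h0 + 1)
        assert conv and len(rows) == 5 and len(cols) == 4

    def test_h_never_increases(self, rng):
        for _ in range(50):
            X = rng.standard_normal((8, 6))
            trace = []
            single_node_deletion(X, range(8), range(6), delta=0.0, trace=trace)
            diffs = np.diff(trace)
            assert np.all(diffs <= 1e-10)

    def test_size_floor_flags_nonconvergence(self, rng):
        X = rng.standard_normal((4, 4))
        rows, cols, conv = single_node_deletion(X, range(4), range(4), delta=1e-12)
        assert not conv
        assert len(rows) == 2 and len(cols) == 2


class TestMultipleNodeDeletion:
    def test_noise_rows_removed_from_additive_block(self, rng):
        kept_frac = []
        for _ in range(10):
            base = np.add.outer(rng.standard_normal(150), rng.standard_normal(20))
            noise = rng.standard_normal((30, 20)) * 3
            X = np.vstack([base, noise])
            rows, cols = multiple_node_deletion(
                X, range(180), range(20), delta=0.01, size_threshold=100
            )
            rows, cols, conv = single_node_deletion(X, rows, cols, delta=0.01)
            assert msr(X, rows, cols)[0] <= 0.01
            kept_frac.append(np.mean([r < 150 for r in rows]) * len(rows) / 150)
        assert np.mean(kept_frac) >= 0.95

    def test_infinite_alpha_is_identity(self, rng):
        X = rng.standard_normal((120, 10))
        rows, cols = multiple_node_deletion(
            X, range(120), range(10), delta=1e-9, alpha=1e12
        )
        assert len(rows) == 120 and len(cols) == 10

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            multiple_node_deletion(np.eye(3), range(3), range(3), 0.1, alpha=0.9)


class TestNodeAddition:
    def test_readds_row_of_additive_matrix(self):
        X = np.add.outer(np.arange(3.0), np.arange(4.0))
        rows, cols = node_addition(X, [0, 1], range(4))
        assert set(rows) == {0, 1, 2}
        assert msr(X, rows, cols)[0] == pytest.approx(0.0, abs=1e-12)

    def test_unchanged_without_candidates(self, rng):
        X = rng.standard_normal((6, 5)) * 10
        X[:3, :3] = np.add.outer(np.arange(3.0), np.arange(3.0))
        rows, cols = node_addition(X, [0, 1, 2], [0, 1, 2])
        assert set(rows) == {0, 1, 2} and set(cols) == {0, 1, 2}

    def test_addition_never_raises_h_above_entry(self, rng):
        for _ in range(50):
            X = rng.standard_normal((20, 10))
            X[:8, :5] += np.add.outer(rng.standard_normal(8), rng.standard_normal(5)) * 2
            trace = []
            node_addition(X, range(4), range(3), trace=trace)
            assert trace[-1] <= trace[0] + 1e-10


class TestFindBicluster:
    def test_whole_matrix_below_delta_returned_entirely(self, rng):
        X = rng.standard_normal((10, 6)) * 0.01
        bc = find_bicluster(X, delta=1.0)
        assert bc.n_rows == 10 and bc.n_cols == 6

    def test_zero_delta_flags_nonconvergence(self, rng):
        X = rng.standard_normal((10, 6))
        bc = find_bicluster(X, delta=1e-14)
        assert not bc.converged

    def test_reported_msr_is_consistent(self, small_cohort, rng):
        X = rng.standard_normal((40, 12))
        bc = find_bicluster(X, delta=0.5)
        h, _, _ = msr(X, bc.rows, bc.cols)
        assert bc.msr == pytest.approx(h, abs=1e-10)
        assert 0.0 <= bc.r2 <= 1.0


def exhaustive_best_msr(X, delta):
    """True/False: does any >=2x2 submatrix achieve MSR <= delta?"""
    m, n = X.shape
    for rk in range(2, m + 1):
        for rows in itertools.combinations(range(m), rk):
            for ck in range(2, n + 1):
                for cols in itertools.combinations(range(n), ck):
                    if msr(X, rows, cols)[0] <= delta:
                        return True
    return False


class TestExclusiveExtraction:
    def test_partition_invariants(self, rng):
        X = rng.standard_normal((60, 15))
        X[:20, :6] += np.add.outer(rng.standard_normal(20), rng.standard_normal(6)) * 2
        bset = find_exclusive_biclusters(X, delta=0.3, max_k=4)
        all_rows = []
        for bc in bset.biclusters:
            assert bc.msr <= 0.3 + 1e-12
            all_rows.extend(bc.rows)
        assert len(all_rows) == len(set(all_rows))  # pairwise disjoint
        assert sorted(all_rows + list(bset.unassigned_rows)) == list(range(60))

    def test_max_k_one(self, rng):
        X = rng.standard_normal((30, 10))
        bset = find_exclusive_biclusters(X, delta=0.5, max_k=1)
        assert len(bset) == 1
        assert sorted(bset.biclusters[0].rows + bset.unassigned_rows) == list(range(30))

    def test_delta_out_of_range_reports_msr_max(self, rng):
        X = rng.standard_normal((20, 8))
        h, _, _ = msr(X, range(20), range(8))
        with pytest.raises(ValueError, match="msr_max"):
            find_exclusive_biclusters(X, delta=h + 1)

    def test_shift_invariance_of_extraction(self, rng):
        X = rng.standard_normal((40, 10))
        X[:15, :4] += np.add.outer(rng.standard_normal(15), rng.standard_normal(4)) * 2
        b1 = find_exclusive_biclusters(X, delta=0.3, max_k=3)
        b2 = find_exclusive_biclusters(X + 5.0, delta=0.3, max_k=3)
        assert [bc.rows for bc in b1.biclusters] == [bc.rows for bc in b2.biclusters]
        assert [bc.cols for bc in b1.biclusters] == [bc.cols for bc in b2.biclusters]

    def test_greedy_succeeds_when_exhaustive_optimum_exists(self, rng):
        # on tiny matrices, whenever some >=2x2 submatrix reaches the
        # threshold, the greedy search must return one that does too
        hits = checks = 0
        for _ in range(200):
            X = rng.integers(0, 3, size=(6, 5)).astype(float)
            if exhaustive_best_msr(X, 0.2):
                checks += 1
                bc = find_bicluster(X, delta=0.2)
                hits += bc.converged and bc.msr <= 0.2 + 1e-12
        assert checks > 0
        assert hits == checks

    def test_roundtrip_serialization(self, rng):
        X = rng.standard_normal((30, 8))
        bset = find_exclusive_biclusters(X, delta=0.5, max_k=2)
        from kneephen.biclustering import BiclusterSet

        back = BiclusterSet.from_dict(bset.to_dict())
        assert back.to_dict() == bset.to_dict()
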