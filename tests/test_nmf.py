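"""NNDSVD initialization, HALS factorization and sparsity diagnostics."""

import warnings

import numpy as np
import pytest
from helpers import matched_cosines

from epicode import (
    SparseNMF,
    hoyer_sparsity,
    matrix_sparsity,
    nmf,
    nndsvd_init,
    nnls_weights,
    rank_scan,
)


class TestHoyerSparsity:
    @pytest.mark.parametrize(
        "v,expected",
        [
            ([1, 0, 0, 0], 1.0),
            ([5, 5, 5, 5], 0.0),
            ([3, 1, 0, 0], (2 - 4 / np.sqrt(10)) / 1),
        ],
    )
    def test_values(self, v, expected):
        assert hoyer_sparsity(np.array(v, float)) == pytest.approx(expected)

    def test_bounds_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = hoyer_sparsity(rng.uniform(0, 1, rng.integers(2, 40)))
            assert 0 <= s <= 1

    def test_single_entry_rejected(self):
        with pytest.raises(ValueError):
            hoyer_sparsity(np.array([1.0]))

    def test_zero_vector_warns(self):
        with pytest.warns(UserWarning):
            assert hoyer_sparsity(np.zeros(4)) == 0.0


class TestMatrixSparsity:
    def test_identity_and_constant(self):
        assert matrix_sparsity(np.eye(4)) == pytest.approx(1.0)
        assert matrix_sparsity(np.ones((3, 5))) == pytest.approx(0.0)

    def test_mixed_rows_average(self):
        M = np.array([[1, 0, 0, 0], [2, 2, 2, 2]], dtype=float)
        assert matrix_sparsity(M) == pytest.approx(0.5)

    def test_zero_rows_skipped(self):
        M = np.array([[1, 0], [0, 0]], dtype=float)
        with pytest.warns(UserWarning, match="skipped"):
            assert matrix_sparsity(M) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            matrix_sparsity(np.zeros((2, 2)))


class TestNNDSVD:
    def test_plain_is_deterministic(self, planted):
        V, _ = planted
        W1, H1 = nndsvd_init(V, 3)
        W2, H2 = nndsvd_init(V, 3)
        assert np.array_equal(W1, W2) and np.array_equal(H1, H2)

    def test_rank1_outer_product_exact(self):
        rng = np.random.default_rng(2)
        w, h = rng.uniform(0.1, 1, 30), rng.uniform(0.1, 1, 6)
        V = np.outer(w, h)
        W0, H0 = nndsvd_init(V, 1)
        assert np.linalg.norm(V - W0 @ H0) / np.linalg.norm(V) < 1e-8

    def test_ar_seeded_and_touches_only_zeros(self, planted):
        V, _ = planted
        Wp, Hp = nndsvd_init(V, 3, "plain")
        Wa1, Ha1 = nndsvd_init(V, 3, "ar", seed=1)
        Wa2, Ha2 = nndsvd_init(V, 3, "ar", seed=1)
        Wb, Hb = nndsvd_init(V, 3, "ar", seed=2)
        assert np.array_equal(Wa1, Wa2) and np.array_equal(Ha1, Ha2)
        nz = Hp != 0
        assert np.array_equal(Ha1[nz], Hp[nz]) and np.array_equal(Hb[nz], Hp[nz])
        assert np.all(Ha1[~nz] > 0) and not np.array_equal(Ha1[~nz], Hb[~nz])
        avg = V.values.mean()
        assert np.all(Ha1[~nz] <= avg / 100) and np.all(Wa1[Wp == 0] <= avg / 100)

    def test_rank_bound_enforced(self, planted):
        V, _ = planted
        with pytest.raises(ValueError):
            nndsvd_init(V, 9)


class TestNMF:
    def test_rank1_exact_reconstruction(self):
        rng = np.random.default_rng(4)
        V = np.outer(rng.uniform(0.1, 0.9, 50), rng.uniform(0.1, 0.9, 5))
        res = nmf(V, 1, l1_h=0.0)
        assert res.reconstruction_error < 1e-6

    def test_objective_trace_monotone(self, planted):
        V, _ = planted
        for init, seed in [("nndsvd", None), ("random", 0), ("nndsvdar", 0)]:
            res = nmf(V, 3, init=init, seed=seed)
            assert np.all(np.diff(res.objective_trace) <= 1e-10)

    def test_factors_nonnegative(self, planted):
        V, _ = planted
        for init in ("nndsvd", "random"):
            res = nmf(V, 4, init=init, seed=3)
            assert np.all(res.W >= 0) and np.all(res.H >= 0)

    def test_planted_recovery_noise_free(self, planted_clean):
        V, truth = planted_clean
        res = nmf(V, 3)
        assert matched_cosines(res.H, truth.H_true).min() >= 0.99

    def test_all_zero_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            nmf(np.zeros((5, 3)), 2)
        with pytest.raises(ValueError):
            nmf(np.array([[1.0, np.nan], [0.5, 1.0]]), 1)

    def test_zero_rows_of_v_give_zero_weights(self):
        rng = np.random.default_rng(5)
        V = rng.uniform(0, 0.9, (30, 5))
        V[[3, 17]] = 0.0
        res = nmf(V, 2)
        assert np.all(res.W[[3, 17]] == 0)

    def test_higher_l1_never_less_sparse(self, planted):
        """Mean Hoyer sparsity of H is monotone in the l1 penalty weight."""
        V, _ = planted
        sparsities = [nmf(V, 3, l1_h=l).sparsity_h() for l in (0.0, 0.5, 2.0)]
        assert sparsities[0] <= sparsities[1] + 1e-9
        assert sparsities[1] <= sparsities[2] + 1e-9

    def test_agrees_with_reference_nmf(self, planted):
        """Independent cross-check against scikit-learn's NMF solver."""
        sklearn_decomposition = pytest.importorskip("sklearn.decomposition")
        V, _ = planted
        ours = nmf(V, 3, l1_h=0.0)
        ref = sklearn_decomposition.NMF(
            n_components=3, init="nndsvd", max_iter=500, tol=1e-6
        )
        ref.fit(V.values)
        assert matched_cosines(ours.H, ref.components_).min() >= 0.9
        ref_err = np.linalg.norm(V.values - ref.transform(V.values) @ ref.components_)
        assert ours.reconstruction_error <= ref_err * 1.05

    def test_summary_reports_fit(self, planted):
        V, _ = planted
        res = SparseNMF(V, 3).fit()
        text = res.summary()
        assert "rank (codes):         3" in text
        assert f"{res.reconstruction_error:.6g}" in text


class TestNNLSWeights:
    def test_identity_basis_returns_v(self):
        rng = np.random.default_rng(6)
        V = rng.uniform(0, 1, (10, 4))
        assert np.allclose(nnls_weights(V, np.eye(4)), V, atol=1e-10)

    def test_recovers_true_weights(self):
        rng = np.random.default_rng(7)
        H = rng.uniform(0, 1, (3, 8))
        Wt = rng.uniform(0, 1, (25, 3))
        W = nnls_weights(Wt @ H, H)
        assert np.allclose(W, Wt, atol=1e-6)

    def test_zero_rows(self):
        rng = np.random.default_rng(8)
        H = np.vstack([rng.uniform(0.1, 1, (2, 5)), np.zeros(5)])
        V = np.vstack([rng.uniform(0, 1, (4, 5)), np.zeros(5)])
        with pytest.warns(UserWarning, match="all-zero basis"):
            W = nnls_weights(V, H)
        assert np.all(W[:, 2] == 0)  # dead code gets zero weight
        assert np.all(W[4] == 0)  # zero locus gets zero row


class TestRankScan:
    def test_record_per_rank_and_rank1_exact(self):
        rng = np.random.default_rng(9)
        V = np.outer(rng.uniform(0.1, 0.9, 40), rng.uniform(0.1, 0.9, 6))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = rank_scan(V, [1, 2, 3], l1_h=0.0)
        assert len(table) == 3
        assert table.reconstruction_error.iloc[0] < 1e-6

    def test_error_non_increasing_in_rank(self, planted):
        V, _ = planted
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = rank_scan(V, [2, 3, 4, 5])
        assert np.all(np.diff(table.reconstruction_error) <= 1e-8)
        assert np.all((table.sparsity_H >= 0) & (table.sparsity_H <= 1))
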