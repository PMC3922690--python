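"""Sigmoid column scaling, size factors and gain/loss construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epicode import (
    GainLossProfile,
    SignalMatrix,
    build_differential_matrix,
    gain_loss,
    scale_matrix,
    sigmoid_scale,
    size_factors,
)
from epicode.regions import CountMatrix


class TestSigmoidScale:
    def test_formula_values(self):
        x = np.array([0.0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10.0, 100.0])
        u = np.percentile(x, 95)
        y = sigmoid_scale(x)
        assert y[0] == 0.0
        # at x = u the sigmoid evaluates to 2/(1+e^-2) - 1
        assert sigmoid_scale(np.array([u, u / 2, u]))[0] == pytest.approx(
            2 / (1 + np.exp(-2)) - 1
        )
        assert np.all((y >= 0) & (y < 1))

    def test_saturation_at_large_values(self):
        x = np.concatenate([np.ones(20), [10.0]])  # u = 1, max = 10u
        y = sigmoid_scale(x)
        assert y[-1] == pytest.approx(1.0, abs=1e-8)
        assert y[-1] < 1.0

    @given(
        st.lists(st.floats(0.01, 1e4), min_size=3, max_size=30),
        st.floats(1e-3, 1e3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, values, alpha):
        x = np.array(values)
        assert np.allclose(sigmoid_scale(alpha * x), sigmoid_scale(x), atol=1e-12)

    def test_monotone(self):
        x = np.sort(np.random.default_rng(0).uniform(0, 5, 50))
        assert np.all(np.diff(sigmoid_scale(x)) >= 0)

    def test_all_zero_column_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert np.all(sigmoid_scale(np.zeros(5)) == 0)

    def test_mostly_zero_column_uses_min_positive(self):
        x = np.array([0.0] * 99 + [7.0])
        with pytest.warns(UserWarning, match="95th percentile is zero"):
            y = sigmoid_scale(x)
        assert y[-1] == pytest.approx(2 / (1 + np.exp(-2)) - 1)


class TestScaleMatrix:
    def test_matches_per_column_evaluation(self):
        vals = np.array([[1, 10], [2, 20], [3, 30]], dtype=float)
        M = CountMatrix(vals.astype(int), ["a", "b", "c"], ["m1", "m2"])
        S = scale_matrix(M)
        assert S.scaled
        for j in range(2):
            assert np.allclose(S.values[:, j], sigmoid_scale(vals[:, j]))

    def test_identical_and_rescaled_columns_agree(self):
        vals = np.column_stack([np.arange(1, 6.0), 3.0 * np.arange(1, 6.0)])
        S = scale_matrix(SignalMatrix(vals, list("abcde"), ["m1", "m2"]))
        assert np.allclose(S.values[:, 0], S.values[:, 1])

    def test_double_scaling_rejected(self):
        S = SignalMatrix(np.full((2, 1), 0.5), ["a", "b"], ["m"], scaled=True)
        with pytest.raises(ValueError, match="already scaled"):
            scale_matrix(S)

    def test_tsv_roundtrip(self, tmp_path):
        S = scale_matrix(
            SignalMatrix(np.arange(6.0).reshape(3, 2), list("abc"), ["m1", "m2"])
        )
        p = tmp_path / "s.tsv"
        S.to_tsv(p)
        back = SignalMatrix.from_tsv(p, scaled=True)
        assert back.row_ids == S.row_ids and back.col_ids == S.col_ids
        assert np.array_equal(back.values, S.values)


class TestSizeFactors:
    def test_hand_example(self):
        K = np.array([[2, 4], [4, 8], [8, 16]], dtype=float)
        f = size_factors(K)
        assert f == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_identical_samples_unit_factors(self):
        K = np.tile(np.arange(1, 6.0)[:, None], (1, 3))
        assert size_factors(K) == pytest.approx([1, 1, 1])

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(0)
        K = rng.integers(1, 100, (30, 3)).astype(float)
        assert size_factors(K[rng.permutation(30)]) == pytest.approx(size_factors(K))

    def test_constant_depth_ratio_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 50, 40).astype(float)
        K = np.column_stack([a, 3.5 * a])
        f = size_factors(K)
        assert f[1] / f[0] == pytest.approx(3.5)

    def test_no_allpositive_row_errors(self):
        K = np.array([[0, 1], [1, 0]], dtype=float)
        with pytest.raises(ValueError, match="coarser"):
            size_factors(K)


class TestGainLoss:
    def test_signed_parts(self):
        p = GainLossProfile("x", np.array([3.0, -1.0, 2.0]))
        assert (p.gain, p.loss) == (5.0, 1.0)

    def test_identical_conditions_zero(self):
        wins = [np.array([3, 4, 5]), np.array([1, 2])]
        for p in gain_loss(wins, wins, (1.0, 1.0)):
            assert p.gain == 0 and p.loss == 0

    def test_gain_minus_loss_is_net_difference(self):
        rng = np.random.default_rng(3)
        wa = [rng.integers(0, 20, 7) for _ in range(5)]
        wb = [rng.integers(0, 20, 7) for _ in range(5)]
        for p, a, b in zip(gain_loss(wa, wb, (0.8, 1.3)), wa, wb):
            net = np.sum(b / 1.3 - a / 0.8)
            assert p.gain - p.loss == pytest.approx(net)

    def test_grid_mismatch_error(self):
        with pytest.raises(ValueError, match="grids"):
            gain_loss([np.zeros(3)], [np.zeros(4)], (1.0, 1.0))


class TestDifferentialMatrix:
    def _profiles(self, diffs_by_mark):
        return {
            mark: [GainLossProfile(f"L{i}", d) for i, d in enumerate(diffs)]
            for mark, diffs in diffs_by_mark.items()
        }

    def test_column_order_and_count(self):
        diffs = [np.array([1.0, -1.0])] * 4
        profs = self._profiles({"a": diffs, "b": diffs, "c": diffs})
        S = build_differential_matrix(profs)
        assert S.col_ids == ["a.gain", "a.loss", "b.gain", "b.loss", "c.gain", "c.loss"]
        assert S.scaled

    def test_single_planted_gain(self):
        diffs = [np.zeros(3) for _ in range(4)]
        diffs[2] = np.array([2.0, 1.0, 0.0])
        with pytest.warns(UserWarning):  # all-zero loss column
            S = build_differential_matrix(self._profiles({"m": diffs}))
        gains = S.values[:, 0]
        assert gains[2] > 0 and np.all(gains[[0, 1, 3]] == 0)
        assert np.all(S.values[:, 1] == 0)

    def test_locus_mismatch_error(self):
        p1 = [GainLossProfile("L1", np.zeros(2)), GainLossProfile("L2", np.ones(2))]
        p2 = [GainLossProfile("L1", np.zeros(2)), GainLossProfile("LX", np.ones(2))]
        with pytest.raises(ValueError, match="locus set"):
            build_differential_matrix({"a": p1, "b": p2})
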