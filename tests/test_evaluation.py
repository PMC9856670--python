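import numpy as np
import pytest

import pshscreen as ps

from conftest import build_dataset


class TestBrier:
    def test_perfect_oracle_zero_error(self, tiny_data):
        grid = np.array([0.5, 2.5, 4.5, 6.5])
        N = (tiny_data.time[:, None] <= grid) & (tiny_data.cause[:, None] == 1)
        curve = ps.brier_cif(tiny_data, N.astype(float), times=grid)
        np.testing.assert_allclose(curve.err, 0.0, atol=1e-15)

    def test_no_censoring_constant_prediction(self):
        data = build_dataset([1, 2, 3, 4, 5], [1, 2, 1, 2, 1])
        q = 0.3
        grid = np.array([2.5])
        pred = np.full((5, 1), q)
        curve = ps.brier_cif(data, pred, times=grid)
        N = ((data.time <= 2.5) & (data.cause == 1)).astype(float)
        assert curve.err[0] == pytest.approx(np.mean((N - q) ** 2), abs=1e-15)

    def test_hand_computed_with_censoring(self):
        # n=4: cause-1 at 1, censored at 2, cause-2 at 3, cause-1 at 4; t=2.5
        data = build_dataset([1.0, 2.0, 3.0, 4.0], [1, 0, 2, 1])
        G = ps.km_censoring(data)
        # G: one censoring at 2 with 3 at risk -> G(t) = 2/3 for t > 2
        assert float(G(2.5)) == pytest.approx(2 / 3)
        pred = np.array([[0.9], [0.2], [0.3], [0.1]])
        grid = np.array([2.5])
        # weights: subj1 event by 2.5 -> 1/G(1)=1; subj2 censored -> 0;
        # subj3, subj4 still at risk -> 1/G(2.5) = 1.5
        expected = ((1 - 0.9) ** 2 * 1.0 + 0.0 + (0 - 0.3) ** 2 * 1.5 + (0 - 0.1) ** 2 * 1.5) / 4
        curve = ps.brier_cif(data, pred, G, grid)
        assert curve.err[0] == pytest.approx(expected, abs=1e-12)

    def test_grid_truncated_where_G_zero(self):
        data = build_dataset([1.0, 2.0], [1, 0])  # G hits 0 after t=2
        with pytest.warns(UserWarning, match="truncated"):
            curve = ps.brier_cif(data, np.zeros((2, 2)), times=[1.5, 3.0])
        assert curve.times.tolist() == [1.5]


def constant_recipe(q):
    def recipe(train):
        def predict(eval_data, times):
            return np.full((eval_data.n, len(np.atleast_1d(times))), q)

        return predict

    return recipe


class TestDot632Plus:
    def test_blend_degeneracies(self):
        from pshscreen.evaluation import dot632plus_blend

        # err_boot == err_app -> R = 0, w = .632, result = err_app
        out = dot632plus_blend([0.2], [0.2], [0.3])
        assert out[0] == pytest.approx(0.2, abs=1e-15)
        # err_boot == err_noinf -> R = 1, w = 1, result = err_boot
        out = dot632plus_blend([0.1], [0.3], [0.3])
        assert out[0] == pytest.approx(0.3, abs=1e-15)

    def test_constant_recipe_close_to_apparent(self):
        """A data-independent prediction rule cannot overfit: the .632+
        estimate stays near the apparent error (not exactly equal, since
        out-of-bag subsets carry their own censoring curves)."""
        data = ps.make_fixture("evaluation")
        grid = np.array([0.5, 1.0])
        curve = ps.dot632plus(data, constant_recipe(0.25), grid, B=10, seed=0)
        app = ps.brier_cif(data, np.full((data.n, 2), 0.25), times=grid)
        np.testing.assert_allclose(curve.err, app.err, rtol=0.05)

    def test_result_between_apparent_and_bootstrap(self):
        data = ps.make_fixture("evaluation")
        grid = np.array([0.4, 0.8, 1.2])

        def recipe(train):
            fit = ps.psh_fit(train, feature_subset=[0, 5, 10, 15])

            def predict(eval_data, times):
                x = eval_data.X.iloc[:, [0, 5, 10, 15]].to_numpy(float)
                lp = fit.linear_predictor(x, eval_data.Z.to_numpy(float))
                H = np.atleast_1d(fit.baseline(np.asarray(times, float)))
                return 1.0 - np.exp(-np.outer(np.exp(lp), H))

            return predict

        curve = ps.dot632plus(data, recipe, grid, B=10, seed=1)
        predict = recipe(data)
        app = ps.brier_cif(data, predict(data, grid), times=grid).err
        assert np.all(curve.err >= app - 1e-9)  # .632+ corrects optimism upward

    def test_null_model_unbiased(self):
        """The covariate-free null model cannot overfit: .632+ stays within
        5% of its apparent error."""
        data = ps.make_fixture("evaluation")
        grid = np.array([0.5, 1.0, 1.5])

        def recipe(train):
            aj = ps.aalen_johansen(train)
            cif1 = aj.cif[1]

            def predict(eval_data, times):
                return np.tile(np.atleast_1d(cif1(np.asarray(times, float))), (eval_data.n, 1))

            return predict

        curve = ps.dot632plus(data, recipe, grid, B=20, seed=2)
        app = ps.brier_cif(data, recipe(data)(data, grid), times=grid).err
        np.testing.assert_allclose(curve.err, app, rtol=0.05)

    def test_requires_two_draws(self, tiny_data):
        with pytest.raises(ValueError, match="B >= 2"):
            ps.dot632plus(tiny_data, constant_recipe(0.1), [1.0], B=1)


def brute_force_weighted_auc(marker, w_case, w_ctrl, cases, ctrls):
    num = den = 0.0
    for i in cases:
        for j in ctrls:
            pair = w_case[i] * w_ctrl[j]
            den += pair
            if marker[i] > marker[j]:
                num += pair
            elif marker[i] == marker[j]:
                num += 0.5 * pair
    return num / den


class TestRoc:
    def test_constant_marker_auc_half(self):
        data = build_dataset([1, 2, 3, 4, 5, 6], [1, 1, 0, 2, 0, 0])
        res = ps.roc_cif(data, np.ones(6), horizon=2.5)
        assert res.auc == pytest.approx(0.5)

    def test_perfect_marker_auc_one(self):
        data = build_dataset([1, 2, 3, 4, 5, 6], [1, 1, 1, 2, 2, 2])
        marker = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        res = ps.roc_cif(data, marker, horizon=3.5)
        assert res.auc == pytest.approx(1.0)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(6, 13))
            time = rng.integers(1, 6, n).astype(float)
            cause = rng.integers(0, 3, n)
            marker = rng.integers(0, 4, n).astype(float)  # force marker ties
            data = build_dataset(time, cause)
            t = 2.5
            is_case = (time <= t) & (cause == 1)
            is_ctrl = (time > t) | ((time <= t) & (cause >= 2))
            if not is_case.any() or not is_ctrl.any():
                continue
            G = ps.km_censoring(data)
            w = np.zeros(n)
            w[is_case] = 1.0 / np.atleast_1d(G(time))[is_case]
            w[is_ctrl & (time > t)] = 1.0 / float(G(t))
            early = is_ctrl & (time <= t)
            w[early] = 1.0 / np.atleast_1d(G(time))[early]
            expected = brute_force_weighted_auc(
                marker, w, w, np.flatnonzero(is_case), np.flatnonzero(is_ctrl)
            )
            res = ps.roc_cif(data, marker, t, G)
            assert res.auc == pytest.approx(expected, abs=1e-12)

    def test_curve_traces_to_corners_and_trapezoid_matches(self):
        data = build_dataset([1, 2, 3, 4, 5, 6, 7], [1, 2, 1, 0, 0, 1, 0])
        marker = np.array([3.0, 1.0, 2.0, 0.5, 2.5, 1.5, 0.0])
        res = ps.roc_cif(data, marker, horizon=3.5)
        assert (res.fpr[0], res.tpr[0]) == (0.0, 0.0)
        assert (res.fpr[-1], res.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)
        trap = np.trapezoid(res.tpr, res.fpr)
        assert res.auc == pytest.approx(trap, abs=1e-12)

    def test_no_cases_raises(self):
        data = build_dataset([5, 6, 7], [1, 0, 2])
        with pytest.raises(ValueError, match="horizon"):
            ps.roc_cif(data, np.arange(3.0), horizon=1.0)
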