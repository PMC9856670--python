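import numpy as np
import pytest
from scipy import optimize

import pshscreen as ps
from pshscreen.simdata import recovery_config

from conftest import build_dataset, random_survival_dataset


def cox_partial_loglik(beta, time, event, X):
    """Independent Breslow-ties Cox partial likelihood (oracle)."""
    beta = np.atleast_1d(beta)
    eta = X @ beta
    ll = 0.0
    for t in np.unique(time[event]):
        here = (time == t) & event
        risk = time >= t
        ll += eta[here].sum() - here.sum() * np.log(np.exp(eta[risk]).sum())
    return ll


def brute_force_cox_fit(time, event, X):
    res = optimize.minimize(
        lambda b: -cox_partial_loglik(b, time, event, X),
        np.zeros(X.shape[1]),
        method="BFGS",
        options={"gtol": 1e-12, "maxiter": 500},
    )
    return res.x


class TestLoglik:
    def test_two_subject_hand_example(self):
        # both cause-1, x = (0, 1), beta = 0: l = log(1/2) + log(1/1)
        data = build_dataset([1.0, 2.0], [1, 1], X=[[0.0], [1.0]])
        ll = ps.psh_loglik([0.0], [], data)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_zero_coefficients_formula(self, tiny_data):
        # at beta = gamma = 0, l = -sum over events of log(weighted risk sum)
        design_ll = ps.psh_loglik([0.0], [0.0], tiny_data)
        sched = ps.fg_weights(tiny_data)
        expected = 0.0
        for t in np.unique(tiny_data.time[tiny_data.cause == 1]):
            d = np.sum((tiny_data.time == t) & (tiny_data.cause == 1))
            w = sched.weight_matrix([t])[:, 0] * sched.risk_matrix([t])[:, 0]
            expected -= d * np.log(w.sum())
        assert design_ll == pytest.approx(expected, abs=1e-12)

    def test_no_events_empty_sum(self):
        data = build_dataset([1, 2, 3], [0, 2, 0], X=[[1.0], [2.0], [0.5]])
        assert ps.psh_loglik([0.3], [], data) == 0.0


class TestFit:
    def test_cox_limit_matches_brute_force(self):
        rng = np.random.default_rng(99)
        for _ in range(8):
            data = random_survival_dataset(rng, n=20, p=2)
            if (data.cause == 1).sum() < 5:
                continue
            fit = ps.psh_fit(data)
            oracle = brute_force_cox_fit(
                data.time, data.cause == 1, data.X.to_numpy(float)
            )
            np.testing.assert_allclose(fit.beta, oracle, atol=1e-6)

    def test_cox_limit_matches_lifelines(self):
        from lifelines import CoxPHFitter

        data = random_survival_dataset(np.random.default_rng(12), n=120, p=3)
        fit = ps.psh_fit(data)
        df = data.X.copy()
        df["T"], df["E"] = data.time, (data.cause == 1).astype(int)
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=5e-5)

    def test_score_zero_and_ascent_at_optimum(self, tiny_data):
        from pshscreen._partial_likelihood import FGDesign

        fit = ps.psh_fit(tiny_data)
        assert fit.converged
        design = FGDesign(tiny_data)
        V = np.hstack([tiny_data.X.to_numpy(float), tiny_data.Z.to_numpy(float)])
        _, U, _ = design.score_information(V, fit.coef)
        assert np.abs(U).max() < 1e-6
        # likelihood ascent: fitted >= null >= zero start
        null = ps.psh_fit(tiny_data, feature_subset=[])
        assert fit.loglik >= null.loglik - 1e-12
        assert null.loglik >= ps.psh_loglik([0.0], [0.0], tiny_data) - 1e-12

    def test_parameter_recovery_small_replicates(self):
        est = [ps.psh_fit(ps.simulate(recovery_config(n=1000, seed=s))).beta[0] for s in range(20)]
        assert abs(np.mean(est) - 0.5) < 0.08  # coarse; the 200-rep check is elsewhere

    def test_rmse_decreases_with_n(self):
        def rmse(n, reps=15):
            err = [
                ps.psh_fit(ps.simulate(recovery_config(n=n, seed=1000 + s))).beta[0] - 0.5
                for s in range(reps)
            ]
            return np.sqrt(np.mean(np.square(err)))

        assert rmse(1000) < rmse(250)

    def test_separation_flagged(self):
        # single feature perfectly ordering cause-1 events before the rest
        data = build_dataset(
            [1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0],
            X=[[3.0], [2.5], [2.0], [0.5], [0.2], [0.0]],
        )
        fit = ps.psh_fit(data)
        assert not fit.converged

    def test_constant_column_rejected(self):
        data = build_dataset([1, 2, 3, 4], [1, 0, 1, 2], X=np.ones((4, 1)))
        with pytest.raises(ValueError, match="constant"):
            ps.psh_fit(data)

    def test_too_many_coefficients_rejected(self):
        data = build_dataset([1, 2, 3, 4], [1, 0, 0, 0], X=np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError, match="identifiable"):
            ps.psh_fit(data)


class TestPredictCIF:
    def test_zero_time_and_unit_hazard(self, tiny_data):
        fit = ps.psh_fit(tiny_data)
        cif = ps.predict_cif(fit, [0.5], [1.0], times=[0.0, 1.0, 3.0, 8.0])
        assert float(cif(0.0)) == 0.0
        # at zero covariates the CIF is exactly 1 - exp(-H10)
        cif0 = ps.predict_cif(fit, [0.0], [0.0], times=[3.0])
        assert float(cif0(3.0)) == pytest.approx(1.0 - np.exp(-float(fit.baseline(3.0))))

    def test_monotone_in_bounds(self, tiny_data):
        fit = ps.psh_fit(tiny_data)
        grid = np.linspace(0, 10, 40)
        vals = np.atleast_1d(ps.predict_cif(fit, [2.0], [1.0], grid)(grid))
        assert np.all(np.diff(vals) >= -1e-15)
        assert np.all((vals >= 0) & (vals < 1))


class TestEstimatorAPI:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        data = random_survival_dataset(np.random.default_rng(3), n=60, p=2)
        est = ps.FineGrayPSH(max_iter=50)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
        X, y = data.X.to_numpy(float), data.y
        est.fit(X, y)
        assert est.coef_.shape == (2,)
        assert est.predict(X).shape == (60,)
        cif = est.predict_cif(X[:3], [1.0, 2.0])
        assert cif.shape == (3, 2)
        assert np.all((cif >= 0) & (cif < 1))

    def test_summary_table_layout(self, tiny_data):
        fit = ps.psh_fit(tiny_data)
        table = fit.summary()
        assert list(table.columns) == [
            "term", "coef", "hazard_ratio", "naive_se", "ci_lower", "ci_upper", "p_value",
        ]
        assert np.allclose(table["hazard_ratio"], np.exp(table["coef"]))
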