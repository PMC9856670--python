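import subprocess

import numpy as np
import pandas as pd
import pytest

import pshscreen as ps

from conftest import build_dataset


class TestAalenJohansen:
    def test_single_cause_no_censoring_is_ecdf(self):
        times = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        data = build_dataset(times, [1] * 5)
        aj = ps.aalen_johansen(data)
        for t in [0.5, 1.0, 3.5, 5.0, 9.0]:
            assert float(aj.cif[1](t)) == pytest.approx(np.mean(times <= t))

    def test_hand_recursion_four_subjects(self):
        # cause-1 at 1, cause-2 at 2, censored at 3, cause-1 at 4
        data = build_dataset([1.0, 2.0, 3.0, 4.0], [1, 2, 0, 1])
        aj = ps.aalen_johansen(data)
        # S(1-)=1, CIF1 jumps 1/4; S(1)=3/4; at t=2 CIF2 jumps (3/4)(1/3)=1/4
        # S(2)=1/2; censoring at 3; at t=4 risk set {4}: CIF1 jumps S(3-)·1/1
        # S(4-) = 1/2 (censoring does not move S)
        assert float(aj.cif[1](1.0)) == pytest.approx(0.25)
        assert float(aj.cif[2](2.0)) == pytest.approx(0.25)
        assert float(aj.cif[1](4.0)) == pytest.approx(0.25 + 0.5)
        assert float(aj.survival(4.0)) == pytest.approx(0.0)

    def test_additivity_at_event_times(self):
        data = ps.make_fixture("evaluation")
        aj = ps.aalen_johansen(data)
        ts = aj.survival.jump_times
        total = np.atleast_1d(aj.survival(ts)).copy()
        for fn in aj.cif.values():
            total += np.atleast_1d(fn(ts))
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_matches_lifelines(self):
        from lifelines import AalenJohansenFitter

        data = ps.make_fixture("evaluation")
        aj = ps.aalen_johansen(data)
        ajf = AalenJohansenFitter(calculate_variance=False).fit(
            data.time, data.cause, event_of_interest=1
        )
        ts = np.unique(data.time[data.cause >= 1])
        theirs = ajf.cumulative_density_.iloc[:, 0]
        theirs = theirs[~theirs.index.duplicated(keep="last")].reindex(ts, method="ffill")
        np.testing.assert_allclose(np.atleast_1d(aj.cif[1](ts)), theirs.to_numpy(), atol=1e-10)


def _cmprsk_gray(data, group):
    """Independent oracle: Gray's test as implemented in R cmprsk."""
    df = pd.DataFrame({"time": data.time, "cause": data.cause, "group": group})
    csv = df.to_csv(index=False)
    script = (
        'd <- read.csv("stdin"); suppressMessages(library(cmprsk));'
        "z <- cuminc(d$time, d$cause, d$group, cencode=0);"
        'cat(z$Tests[1,1], z$Tests[1,2], "\\n")'
    )
    out = subprocess.run(
        ["Rscript", "-e", script], input=csv, capture_output=True, text=True, check=True
    )
    stat, p = (float(v) for v in out.stdout.split())
    return stat, p


class TestGrayTest:
    def test_one_group_rejected(self, tiny_data):
        with pytest.raises(ValueError, match="2 groups"):
            ps.gray_test(tiny_data, ["A"] * tiny_data.n)

    def test_identical_copies_statistic_zero(self):
        base = ps.simulate(ps.SimulationConfig(n=40, p=1, p0=0, beta1={0: 0.5}, censor_max=3.0, seed=3))
        dup = build_dataset(
            np.concatenate([base.time] * 2), np.concatenate([base.cause] * 2)
        )
        res = ps.gray_test(dup, np.repeat(["A", "B"], 40))
        assert res.statistic < 1e-10
        assert res.p_value > 0.999

    def test_invariant_to_relabeling_and_time_rescaling(self):
        data = ps.simulate(ps.SimulationConfig(n=120, p=1, p0=0, beta1={0: 0.8}, censor_max=3.0, seed=9))
        group = np.where(data.X.iloc[:, 0] > 0, "A", "B")
        res = ps.gray_test(data, group)
        swapped = ps.gray_test(data, np.where(group == "A", "Z", "Q"))
        assert res.statistic == pytest.approx(swapped.statistic, rel=1e-12)
        warped = build_dataset(np.expm1(data.time), data.cause)  # strictly increasing map
        res_w = ps.gray_test(warped, group)
        assert res.statistic == pytest.approx(res_w.statistic, rel=1e-9)

    def test_agrees_with_cmprsk_oracle(self):
        """Statistic within ~10% and p-value within 0.02 of R cmprsk (the
        two use different but asymptotically equivalent risk-set weights
        and variance estimators)."""
        for seed in (0, 1, 2):
            data = ps.simulate(
                ps.SimulationConfig(n=300, p=1, p0=0, beta1={0: 0.6}, mixture_mass=0.4,
                                    censor_max=3.0, seed=seed)
            )
            group = np.where(data.X.iloc[:, 0] > 0, "A", "B")
            mine = ps.gray_test(data, group)
            stat_r, p_r = _cmprsk_gray(data, group)
            assert mine.statistic == pytest.approx(stat_r, rel=0.15)
            assert mine.p_value == pytest.approx(p_r, abs=0.02)

    def test_three_group_df(self):
        data = ps.simulate(ps.SimulationConfig(n=150, p=1, p0=0, censor_max=3.0, seed=5))
        rng = np.random.default_rng(0)
        res = ps.gray_test(data, rng.integers(0, 3, data.n))
        assert res.df == 2
        assert 0.0 <= res.p_value <= 1.0

    def test_power_against_strong_separation(self):
        hits = 0
        for s in range(20):
            data = ps.simulate(
                ps.SimulationConfig(n=400, p=1, p0=0, beta1={0: 1.5}, mixture_mass=0.4,
                                    censor_max=3.0, seed=100 + s)
            )
            group = np.where(data.X.iloc[:, 0] > 0, "hi", "lo")
            hits += ps.gray_test(data, group).p_value < 0.001
        assert hits >= 19


class TestStratify:
    def test_even_median_cutoff(self):
        res = ps.stratify([1.0, 2.0, 3.0, 4.0])
        assert res.cutoff == 2.5
        assert res.group.tolist() == ["low", "low", "high", "high"]

    def test_boundary_score_is_low(self):
        res = ps.stratify([1.0, 2.0, 3.0], [2.0])
        assert res.cutoff == 2.0
        assert res.test_group.tolist() == ["low"]

    def test_degenerate_median_warns_not_errors(self):
        with pytest.warns(UserWarning, match="imbalanced"):
            res = ps.stratify([0.0, 0.0, 0.0, 5.0])
        assert res.imbalanced
        assert res.group.tolist() == ["low", "low", "low", "high"]

    def test_identical_scores_error(self):
        with pytest.raises(ValueError, match="identical"):
            ps.stratify([2.0, 2.0, 2.0])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        train, test = rng.standard_normal(21), rng.standard_normal(10)
        base = ps.stratify(train, test)
        warped = ps.stratify(np.exp(train), np.exp(test))
        np.testing.assert_array_equal(base.group, warped.group)
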