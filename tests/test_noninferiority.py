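"""Weighted regression fit, non-inferiority contrast test, simulation harness."""

import numpy as np
import pytest
from scipy import stats

from ginsengq import (
    FUNCTIONS,
    NonInferiorityInput,
    UntestableFunctionError,
    fit_weighted_regression,
    run_function_battery,
    simulate_type1_power,
    test_noninferiority,
)

from conftest import make_record


def make_input(b_black, b_red, s_black=None, s_red=None):
    b = np.concatenate([b_black, b_red]).astype(float)
    g = np.array([0] * len(b_black) + [1] * len(b_red))
    s_black = np.ones(len(b_black)) if s_black is None else np.asarray(s_black, float)
    s_red = np.ones(len(b_red)) if s_red is None else np.asarray(s_red, float)
    return NonInferiorityInput(b=b, g=g, s=np.concatenate([s_black, s_red]))


class TestFit:
    def test_unweighted_group_means(self):
        fit = fit_weighted_regression(make_input([2, 4], [3, 5]))
        assert fit.mu_hat == pytest.approx(3.0)
        assert fit.delta_hat == pytest.approx(1.0)

    def test_weighted_mean_closed_form(self):
        fit = fit_weighted_regression(make_input([0, 6], [3, 3], s_black=[3, 1]))
        assert fit.mu_hat == pytest.approx((3 * 0 + 1 * 6) / 4)

    def test_perfect_fit_zero_variance(self):
        fit = fit_weighted_regression(make_input([4, 4, 4, 4], [4, 4, 4, 4]))
        assert fit.delta_hat == pytest.approx(0.0)
        assert fit.sigma2_hat == pytest.approx(0.0)

    def test_one_group_missing_untestable(self):
        with pytest.raises(UntestableFunctionError):
            NonInferiorityInput(b=[1.0, 2.0, 3.0], g=[1, 1, 1], s=[1, 1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_wls(self, seed):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(seed)
        n0, n1 = rng.integers(3, 30, size=2)
        inp = make_input(
            rng.poisson(8, n0), rng.poisson(10, n1),
            s_black=rng.uniform(0.1, 1, n0), s_red=rng.uniform(0.1, 1, n1),
        )
        fit = fit_weighted_regression(inp)
        X = np.column_stack([np.ones(inp.b.size), inp.g])
        res = sm.WLS(inp.b, X, weights=inp.s).fit()
        assert fit.mu_hat == pytest.approx(res.params[0], abs=1e-10)
        assert fit.delta_hat == pytest.approx(res.params[1], abs=1e-10)
        assert fit.sigma2_hat == pytest.approx(res.scale, rel=1e-10)
        # contrast t and one-sided p via statsmodels as independent oracle
        gamma = 0.8
        tt = res.t_test([1 - gamma, -gamma])
        t_sm = float(np.asarray(tt.tvalue).squeeze())
        mine = test_noninferiority(fit, gamma=gamma)
        assert mine.t_stat == pytest.approx(t_sm, abs=1e-10)
        assert mine.p_value == pytest.approx(float(stats.t.sf(t_sm, res.df_resid)), abs=1e-10)


class TestTestNoninferiority:
    def test_null_boundary_gives_half(self):
        # mu_hat = 8 equals gamma*(mu+delta) = 0.8*10 exactly
        res = test_noninferiority(fit_weighted_regression(make_input([7, 9], [9, 11])), gamma=0.8)
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.5, abs=1e-12)

    def test_black_far_inferior_p_near_one(self):
        res = test_noninferiority(
            fit_weighted_regression(make_input([1, 2, 1, 2], [20, 22, 21, 19])), gamma=0.8
        )
        assert res.t_stat < -5
        assert res.p_value > 0.99

    def test_degenerate_variance_sign_rule(self):
        # identical groups, perfect fit: contrast (1-gamma)*10 > 0 -> p = 0
        res = test_noninferiority(
            fit_weighted_regression(make_input([10] * 4, [10] * 4)), gamma=0.8
        )
        assert res.sigma2_hat == 0.0 and res.p_value == 0.0
        # jittered input approaches the same decision continuously
        jit = test_noninferiority(
            fit_weighted_regression(make_input([10.01, 9.99, 10.01, 9.99], [10.01, 9.99, 10.01, 9.99])),
            gamma=0.8,
        )
        assert jit.p_value < 1e-6
        # negative contrast: black absent evidence, perfect fit -> p = 1
        res_neg = test_noninferiority(
            fit_weighted_regression(make_input([1] * 4, [10] * 4)), gamma=0.8
        )
        assert res_neg.p_value == 1.0

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        s0, s1 = rng.uniform(0.1, 1, 10), rng.uniform(0.1, 1, 12)
        inp1 = make_input(rng.poisson(8, 10), rng.poisson(10, 12), s_black=s0, s_red=s1)
        inp2 = NonInferiorityInput(b=inp1.b, g=inp1.g, s=inp1.s * 37.5)
        r1 = test_noninferiority(fit_weighted_regression(inp1))
        r2 = test_noninferiority(fit_weighted_regression(inp2))
        assert r1.t_stat == pytest.approx(r2.t_stat, abs=1e-10)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-10)

    def test_gamma_out_of_range(self):
        fit = fit_weighted_regression(make_input([2, 4], [3, 5]))
        with pytest.raises(ValueError):
            test_noninferiority(fit, gamma=1.2)


class TestBattery:
    def _corpus(self, rng, skip_black_for=("Antidepressant/Antianxiety",)):
        recs = []
        for function in FUNCTIONS:
            for k in range(6):
                if function not in skip_black_for:
                    recs.append(
                        make_record(
                            record_id=f"b{function}{k}", subject="black", function=function,
                            n_bioassays=int(rng.poisson(8)), score=float(rng.uniform(0.2, 1)),
                        )
                    )
                recs.append(
                    make_record(
                        record_id=f"r{function}{k}", subject="red", function=function,
                        n_bioassays=int(rng.poisson(10)), score=float(rng.uniform(0.2, 1)),
                    )
                )
        return recs

    def test_returns_exactly_eight_rows(self):
        battery = run_function_battery(self._corpus(np.random.default_rng(0)))
        assert len(battery) == 8
        assert list(battery["function"]) == list(FUNCTIONS)

    def test_missing_group_flagged_untestable(self):
        battery = run_function_battery(self._corpus(np.random.default_rng(0)))
        row = battery[battery["function"] == "Antidepressant/Antianxiety"].iloc[0]
        assert row["decision"] == "untestable"
        assert row["n_black"] == 0 and np.isnan(row["p"])
        # all other functions produce a p-value
        others = battery[battery["function"] != "Antidepressant/Antianxiety"]
        assert others["p"].notna().all()

    def test_identical_groups_positive_contrast(self):
        recs = []
        for k in range(8):
            for subject in ("black", "red"):
                recs.append(
                    make_record(
                        record_id=f"{subject}{k}", subject=subject,
                        function="Antioxidant", n_bioassays=5 + (k % 3), score=0.8,
                    )
                )
        battery = run_function_battery(recs)
        row = battery[battery["function"] == "Antioxidant"].iloc[0]
        # delta_hat = 0 so the contrast is (1-gamma)*mu_hat > 0 and p <= 0.5
        assert row["delta_hat"] == pytest.approx(0.0)
        assert row["p"] <= 0.5


class TestSimulation:
    def test_deterministic_under_seed(self):
        a = simulate_type1_power(mu=8, delta=2, sigma=2, n_per_group=10, n_reps=300, seed=5)
        b = simulate_type1_power(mu=8, delta=2, sigma=2, n_per_group=10, n_reps=300, seed=5)
        assert a.n_rejected == b.n_rejected

    def test_boundary_null_close_to_alpha(self):
        sim = simulate_type1_power(
            mu=8, delta=2, gamma=0.8, sigma=2, n_per_group=20, n_reps=2000, alpha=0.05, seed=11
        )
        assert abs(sim.rejection_rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_power_increases_with_n_and_margin_distance(self):
        at_margin = simulate_type1_power(
            mu=8, delta=2, sigma=2, n_per_group=20, n_reps=500, seed=3
        )
        small_n = simulate_type1_power(
            mu=10, delta=-5, sigma=2, n_per_group=5, n_reps=500, seed=3
        )
        large_n = simulate_type1_power(
            mu=10, delta=-5, sigma=2, n_per_group=40, n_reps=500, seed=3
        )
        assert at_margin.rejection_rate < small_n.rejection_rate <= large_n.rejection_rate
        assert large_n.rejection_rate > 0.95

    def test_small_reps_warn(self):
        with pytest.warns(UserWarning):
            sim = simulate_type1_power(mu=8, delta=2, sigma=2, n_per_group=5, n_reps=50, seed=0)
        assert sim.warning is not None

    def test_pvalues_uniform_under_boundary_null(self):
        # direct check of the contrast-test calibration at the boundary null
        rng = np.random.default_rng(21)
        n = 20
        g = np.repeat([0, 1], n)
        pvals = []
        for _ in range(5000):
            s = rng.uniform(0.25, 1.0, 2 * n)
            b = 8 + 2 * g + rng.normal(0, 2 / np.sqrt(s))
            res = test_noninferiority(
                fit_weighted_regression(NonInferiorityInput(b=b, g=g, s=s)), gamma=0.8
            )
            pvals.append(res.p_value)
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.02
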