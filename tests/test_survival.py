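import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from conftest import random_survival_table
from opsccrna.io_core import SurvivalTable
from opsccrna.survival import (
    binarize_by_quantile,
    km_estimator,
    km_survival_at,
    logrank_test,
    rmst,
    rmst_single,
    survival_by_expression,
)
from opsccrna.synthetic import SimulationConfig, gen_survival


def table(times, events, prefix="s"):
    return SurvivalTable(
        pd.DataFrame(
            {"time_months": times, "event": events},
            index=pd.Index([f"{prefix}{i}" for i in range(len(times))], name="sample_id"),
        )
    )


class TestBinarize:
    def test_q3_hand_example(self):
        b = binarize_by_quantile(pd.Series(range(1, 9), index=list("abcdefgh")), 0.75)
        assert b.cutoff == pytest.approx(6.25)
        assert set(b.labels[b.labels == "high"].index) == {"g", "h"}

    def test_median_hand_example(self):
        b = binarize_by_quantile(pd.Series(range(1, 9), index=list("abcdefgh")), 0.5)
        assert b.cutoff == pytest.approx(4.5)
        assert b.n_high == 4 and b.n_low == 4

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            binarize_by_quantile(pd.Series([3.0] * 6, index=list("abcdef")), 0.75)


class TestKm:
    def test_hand_example_no_censoring(self, toy_survival):
        km = km_estimator(toy_survival)
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_at_one(self):
        km = km_estimator(table([5, 6, 7], [0, 0, 0]))
        assert km.times.size == 0
        assert km_survival_at(km, 100.0) == 1.0

    def test_matches_empirical_survival_without_censoring(self):
        """No censoring: KM reduces to the empirical survival function."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            t = random_survival_table(rng, 25, censor_frac=0.0)
            km = km_estimator(t)
            for tau in km.times:
                emp = np.mean(t.time > tau)
                assert km_survival_at(km, tau) == pytest.approx(emp, abs=1e-12)

    def test_matches_lifelines_with_censoring(self):
        rng = np.random.default_rng(22)
        t = random_survival_table(rng, 40, censor_frac=0.4)
        km = km_estimator(t)
        kmf = KaplanMeierFitter().fit(t.time, t.event)
        for tau in km.times:
            assert km_survival_at(km, tau) == pytest.approx(
                float(kmf.predict(tau)), abs=1e-10
            )

    def test_row_order_invariance(self):
        rng = np.random.default_rng(23)
        t = random_survival_table(rng, 30)
        perm = t.data.sample(frac=1, random_state=1)
        np.testing.assert_allclose(
            km_estimator(t).survival, km_estimator(SurvivalTable(perm)).survival
        )


class TestLogrank:
    def test_identical_arms_null(self, toy_survival):
        other = SurvivalTable(toy_survival.data.set_axis(["e", "f", "g", "h"]))
        chisq, p = logrank_test(toy_survival, other)
        assert chisq == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_arms_hand_statistic(self):
        """Events at (1,2) vs (10,11): O-E is (1-1/2)+(1-1/3)=7/6 and the
        variance sums to 17/36, so chi-square = 49/17."""
        a = table([1, 2], [1, 1], "a")
        b = table([10, 11], [1, 1], "b")
        chisq, _ = logrank_test(a, b)
        assert chisq == pytest.approx(49 / 17, abs=1e-12)

    def test_arm_swap_invariance(self):
        rng = np.random.default_rng(31)
        a = random_survival_table(rng, 20)
        b = random_survival_table(rng, 25)
        assert logrank_test(a, b) == pytest.approx(logrank_test(b, a))

    def test_matches_lifelines(self):
        rng = np.random.default_rng(32)
        a = random_survival_table(rng, 30)
        b = random_survival_table(rng, 35)
        chisq, p = logrank_test(a, b)
        ref = ll_logrank(a.time, b.time, event_observed_A=a.event, event_observed_B=b.event)
        assert chisq == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_null_simulation_type_one_error(self):
        """Median-split log-rank under a flat hazard rejects at ~5%."""
        rng = np.random.default_rng(11)
        rej = 0
        reps = 500
        for _ in range(reps):
            cfg = SimulationConfig(
                hazard_coefficient=0.0,
                n_samples_per_group=(50, 50),
                seed=int(rng.integers(2**31)),
            )
            expr = pd.Series(
                np.random.default_rng([cfg.seed, 99]).standard_normal(100),
                index=[f"S{i:03d}" for i in range(100)],
            )
            surv, _ = gen_survival(expr, cfg)
            res = survival_by_expression(expr, surv, q=0.5)
            rej += res["logrank_p"] < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(table([1, 2], [0, 0], "a"), table([3, 4], [0, 0], "b"))


class TestRmst:
    def test_flat_curve_equals_tau(self):
        t = table([20, 25, 30], [0, 0, 0])
        assert rmst_single(t, 10.0) == pytest.approx(10.0)

    def test_hand_step_integral(self, toy_survival):
        assert rmst_single(toy_survival, 4.0) == pytest.approx(2.5)

    def test_no_censoring_equals_mean_truncated_time(self):
        """tau at the maximum: RMST equals mean(min(T, tau)) exactly."""
        rng = np.random.default_rng(41)
        for _ in range(20):
            t = random_survival_table(rng, 30, censor_frac=0.0)
            tau = float(t.time.max())
            assert rmst_single(t, tau) == pytest.approx(
                np.minimum(t.time, tau).mean(), abs=1e-12
            )

    def test_monotone_in_tau(self):
        rng = np.random.default_rng(42)
        t = random_survival_table(rng, 30)
        taus = np.linspace(1, t.time.max(), 15)
        vals = [rmst_single(t, tau) for tau in taus]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_default_tau_is_smaller_arm_maximum(self):
        a = table([5, 10, 15], [1, 1, 1], "a")
        b = table([3, 8], [1, 1], "b")
        assert rmst(a, b).tau == pytest.approx(8.0)

    def test_difference_is_low_minus_high(self, toy_survival):
        late = table([10, 11, 12, 13], [1, 1, 1, 1], "b")
        r = rmst(late, toy_survival, tau=4.0)  # low arm survives longer
        assert r.difference == pytest.approx(r.rmst_low - r.rmst_high)
        assert r.difference > 0

    def test_high_expression_arm_has_lower_rmst_under_hazard(self):
        """With a positive expression hazard, the high arm loses RMST in at
        least 95% of 100 simulated cohorts of 200."""
        ok = 0
        for seed in range(100):
            cfg = SimulationConfig(hazard_coefficient=1.0, seed=seed)
            expr = pd.Series(
                np.random.default_rng([seed, 98]).standard_normal(200),
                index=[f"S{i:03d}" for i in range(200)],
            )
            surv, _ = gen_survival(expr, cfg)
            ok += survival_by_expression(expr, surv, q=0.75)["rmst"].difference > 0
        assert ok >= 95

    def test_nonpositive_tau_rejected(self, toy_survival):
        with pytest.raises(ValueError):
            rmst_single(toy_survival, 0.0)
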