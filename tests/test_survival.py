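"""Cox ridge fitting, bootstrap signatures, KM and log-rank -- with
lifelines as the independent cross-check where it implements the same
estimator."""

import numpy as np
import pandas as pd
import pytest

from retromir.simulate import SimConfig, SurvivalSpec, simulate_survival
from retromir.survival import (
    bootstrap_signature,
    evaluate_signature,
    fit_cox_ridge,
    km_estimate,
    logrank_test,
    median_survival,
    score_patients,
)


class TestKM:
    def test_hand_computed_with_censoring(self):
        # times {1, 2+, 3}: S(1) = 2/3, the censored subject leaves, S(3) = 0
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert km.survival.tolist() == pytest.approx([2 / 3, 0.0])

    def test_no_events_flat_curve(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert len(km) == 0  # S(t) = 1 everywhere

    def test_product_limit_distinct_events(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert km.survival.tolist() == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(100, 80)
        e = (rng.random(80) < 0.7).astype(int)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in km.iterrows():
            assert row.survival == pytest.approx(
                float(kmf.survival_function_at_times(row.time).iloc[0])
            )

    def test_median_survival(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert median_survival(km) == 2.0


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 5]
        chi2, p = logrank_test(t, [1] * 5, t, [1] * 5)
        assert chi2 == 0 and p == 1

    def test_hand_computed_separated_groups(self):
        chi2, _ = logrank_test([1, 2, 3], [1, 1, 1], [10, 20, 30], [1, 1, 1])
        # all three A-events happen while both groups are fully at risk
        # O_A - E_A = 3 - (3/6 + 2/5 + 1/4); V = sum of hypergeometric vars
        e = 3 / 6 + 2 / 5 + 1 / 4
        v = (3 * 3 / 36 * 5 / 5) + (2 * 3 / 25 * 4 / 4) + (1 * 3 / 16 * 3 / 3)
        assert chi2 == pytest.approx((3 - e) ** 2 / v)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1], [1])

    def test_time_rescaling_invariance(self, rng):
        t1 = rng.exponential(50, 40)
        t2 = rng.exponential(80, 40)
        e1 = (rng.random(40) < 0.8).astype(int)
        e2 = (rng.random(40) < 0.8).astype(int)
        a = logrank_test(t1, e1, t2, e2)
        b = logrank_test(t1 * 7.5, e1, t2 * 7.5, e2)
        assert a == pytest.approx(b)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        t1 = rng.exponential(50, 60)
        t2 = rng.exponential(90, 60)
        e1 = (rng.random(60) < 0.8).astype(int)
        e2 = (rng.random(60) < 0.8).astype(int)
        chi2, p = logrank_test(t1, e1, t2, e2)
        ref = ll_logrank(t1, t2, e1, e2)
        assert chi2 == pytest.approx(ref.test_statistic)
        assert p == pytest.approx(ref.p_value)


def simulate_cox_data(rng, n, beta, censor_scale=3.0):
    x = rng.normal(size=n)
    T = rng.exponential(np.exp(-beta * x))
    C = rng.exponential(censor_scale, n)
    return np.minimum(T, C), (T <= C).astype(int), x[:, None]


class TestCoxRidge:
    def test_recovers_known_effect(self, rng):
        t, e, X = simulate_cox_data(rng, 500, np.log(2))
        beta = fit_cox_ridge(t, e, X, lam=1e-4)
        assert beta[0] == pytest.approx(np.log(2), abs=0.15)

    def test_duplication_invariance(self, rng):
        t, e, X = simulate_cox_data(rng, 120, 0.5)
        b1 = fit_cox_ridge(t, e, X, lam=0.1)
        b2 = fit_cox_ridge(np.r_[t, t], np.r_[e, e], np.vstack([X, X]), lam=0.1)
        assert b1 == pytest.approx(b2, abs=1e-6)

    def test_needs_two_events(self):
        with pytest.raises(ValueError, match="events"):
            fit_cox_ridge(np.array([1.0, 2.0]), np.array([1, 0]), np.zeros((2, 1)))

    def test_matches_lifelines_at_small_penalty(self, rng):
        from lifelines import CoxPHFitter

        t, e, X = simulate_cox_data(rng, 300, 0.7)
        beta = fit_cox_ridge(t, e, X, lam=1e-8)
        df = pd.DataFrame({"T": t, "E": e, "x": X[:, 0]})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert beta[0] == pytest.approx(cph.params_["x"], abs=1e-3)


@pytest.fixture(scope="module")
def surv_df():
    cfg = SimConfig()
    rng = np.random.default_rng(7)
    df, truth = simulate_survival(cfg, rng, [f"f{i}" for i in range(5)])
    return df, truth


class TestBootstrapSignature:
    def test_deterministic_under_seed(self, surv_df):
        df, _ = surv_df
        feats = [c for c in df.columns if c.startswith("f")]
        m1 = bootstrap_signature(df, feats, n_boot=30, seed=11)
        m2 = bootstrap_signature(df, feats, n_boot=30, seed=11)
        assert m1 == m2

    def test_planted_feature_selected(self, surv_df):
        df, truth = surv_df
        feats = [c for c in df.columns if c.startswith("f")]
        planted = truth[0]["feature"]
        model = bootstrap_signature(df, feats, n_boot=50, seed=3)
        assert planted in model.features
        assert model.coefficients[planted] > 0

    def test_all_null_features_usually_empty(self):
        rng = np.random.default_rng(5)
        cfg = SimConfig(survival=SurvivalSpec(beta=0.0, n_patients=150))
        empty = 0
        runs = 10
        for r in range(runs):
            rng2 = np.random.default_rng(100 + r)
            df, _ = simulate_survival(cfg, rng2, [f"f{i}" for i in range(5)])
            m = bootstrap_signature(df, [f"f{i}" for i in range(5)], n_boot=100, seed=r)
            empty += not m.features
        assert empty >= 0.8 * runs


class TestEvaluate:
    def test_median_split_tie_rule(self):
        df = pd.DataFrame({"time": [5, 6, 7, 8.0], "event": [1, 1, 1, 1],
                           "f0": [1.0, 2.0, 3.0, 4.0]})
        model = bootstrap_signature(df, ["f0"], n_boot=10, seed=0)
        model.features, model.coefficients = ["f0"], {"f0": 1.0}
        ev = evaluate_signature(model, df)
        assert ev.high_mask.tolist() == [False, False, True, True]

    def test_planted_effect_direction(self, rng):
        cfg = SimConfig()
        df, truth = simulate_survival(cfg, rng, [f"f{i}" for i in range(5)])
        model = bootstrap_signature(df, [f"f{i}" for i in range(5)], n_boot=50, seed=2)
        ev = evaluate_signature(model, df)
        # high-score patients carry the hazardous feature: worse survival
        assert ev.median_high < ev.median_low
        assert ev.p < 0.05
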