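"""Survival-statistics tests against closed-form, grid-search and
brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats

from sigentropy.errors import (
    ConvergenceError,
    StratificationError,
    UndefinedTestError,
)
from sigentropy.survival import (
    SurvivalCohort,
    c_index_se,
    censor_at,
    compare_scores_meta,
    concordance_index,
    cox_fit,
    fisher_combined,
    hazard_ratio,
    meta_random_effects,
    tertile_stratify,
)
from sigentropy.synthetic import make_two_group_cohort, simulate_survival


def cohort_from(time, event, **cols):
    df = pd.DataFrame({"time": time, "event": event, **cols})
    df.index = [f"s{i}" for i in range(len(df))]
    return SurvivalCohort(df)


def breslow_neg_loglik(beta, time, event, x):
    """Oracle: Breslow partial log-likelihood, direct evaluation."""
    ll = 0.0
    eta = beta * np.asarray(x, float)
    for i in np.flatnonzero(event):
        risk = np.asarray(time, float) >= time[i]
        ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return -ll


def cindex_bruteforce(scores, time, event):
    """Oracle: exhaustive pair enumeration."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


class TestCensorAt:
    def test_late_event_becomes_censored(self):
        c = censor_at(cohort_from([7.0, 3.0], [1, 1]), 5.0)
        assert list(c.time) == [5.0, 3.0]
        assert list(c.event) == [0, 1]

    def test_never_increases_time_or_creates_events(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(3, 50)
        e = rng.integers(0, 2, 50)
        c = censor_at(cohort_from(t, e), 2.5)
        assert np.all(c.time <= t)
        assert np.all(c.event <= e)

    def test_horizon_at_min_time(self):
        c = censor_at(cohort_from([1.0, 2.0, 3.0], [1, 1, 1]), 1.0)
        assert list(c.event) == [1, 0, 0]
        assert list(c.time) == [1.0, 1.0, 1.0]


class TestCoxFit:
    def test_closed_form_fixture(self):
        # score equation for this design reduces to u^2 - u - 4 = 0, u = e^beta
        c = cohort_from([1, 2, 3, 4], [1, 1, 1, 1], x=[1.0, 0.0, 1.0, 0.0])
        fit = cox_fit(c, ["x"])
        assert fit.params["x"] == pytest.approx(np.log((1 + np.sqrt(17)) / 2), abs=1e-4)

    def test_matches_grid_search_oracle_on_small_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = 6
            t = rng.exponential(1, n) + 0.01
            e = np.ones(n, dtype=int)
            x = rng.normal(size=n)
            fit = cox_fit(cohort_from(t, e, x=x), ["x"])
            res = scipy.optimize.minimize_scalar(
                breslow_neg_loglik, bounds=(-10, 10), args=(t, e, x),
                method="bounded", options={"xatol": 1e-10},
            )
            assert fit.params["x"] == pytest.approx(res.x, abs=1e-4)

    def test_separation_raises(self):
        c = cohort_from([1.0, 2.0], [1, 1], x=[1.0, 0.0])
        with pytest.raises(ConvergenceError):
            cox_fit(c, ["x"])

    def test_null_covariate_wald_p_roughly_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for rep in range(100):
            n = 80
            x = rng.normal(size=n)
            t, e = simulate_survival(np.zeros(n), 0.3, 0.2, rng)
            ps.append(cox_fit(cohort_from(t, e, x=x), ["x"]).pvalues["x"])
        # KS against uniform; generous threshold for 100 reps
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_categorical_covariate_one_hot(self):
        rng = np.random.default_rng(3)
        n = 120
        grp = rng.choice(["a", "b"], n)
        t, e = simulate_survival(np.where(grp == "b", 0.7, 0.0), 0.2, 0.2, rng)
        fit = cox_fit(cohort_from(t, e, g=grp), ["g"])
        assert "g_b" in fit.params.index
        assert fit.params["g_b"] == pytest.approx(0.7, abs=0.5)


class TestConcordance:
    def test_perfectly_concordant(self):
        c = cohort_from([1, 2, 3], [1, 1, 1])
        assert concordance_index([3, 2, 1], c) == 1.0

    def test_all_tied_scores(self):
        c = cohort_from([1, 2, 3], [1, 1, 1])
        assert concordance_index([5, 5, 5], c) == 0.5

    def test_censoring_comparability(self):
        # pairs via the t=1 event only; t=2 censored vs t=3 not comparable
        c = cohort_from([1, 2, 3], [1, 0, 1])
        assert concordance_index([1, 3, 2], c) == pytest.approx(
            cindex_bruteforce([1, 3, 2], [1, 2, 3], [1, 0, 1])
        )
        assert concordance_index([1, 3, 2], c) == 0.0

    def test_matches_bruteforce_and_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = 50
            t = rng.exponential(1, n)  # continuous: no ties
            e = rng.integers(0, 2, n)
            e[0] = 1
            s = rng.normal(size=n)
            c = cohort_from(t, e)
            ours = concordance_index(s, c)
            assert ours == pytest.approx(cindex_bruteforce(s, t, e), abs=1e-15)
            theirs = lifelines.utils.concordance_index(t, -s, e)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_comparable_pairs(self):
        with pytest.raises(UndefinedTestError):
            concordance_index([1, 2], cohort_from([1.0, 2.0], [0, 0]))

    def test_bootstrap_ci_excludes_half_for_strong_signal(self):
        rng = np.random.default_rng(5)
        n = 150
        risk = rng.normal(size=n)
        t, e = simulate_survival(2.0 * risk, 0.2, 0.2, rng)
        c = cohort_from(t, e)
        se, (lo, hi) = c_index_se(risk, c, B=200, seed=1)
        assert lo > 0.5
        assert se > 0

    def test_bootstrap_needs_enough_resamples(self):
        with pytest.raises(ValueError):
            c_index_se([1, 2, 3], cohort_from([1, 2, 3], [1, 1, 1]), B=1)


class TestTertiles:
    def test_nine_scores_split_evenly(self):
        g = tertile_stratify(np.arange(1, 10))
        assert list(g.value_counts()[["low", "mid", "high"]]) == [3, 3, 3]

    def test_constant_scores_rejected(self):
        with pytest.raises(StratificationError):
            tertile_stratify([2.0, 2.0, 2.0])

    def test_ten_scores_deterministic_quantile_convention(self):
        s = np.arange(1, 11).astype(float)
        q1, q2 = np.quantile(s, [1 / 3, 2 / 3], method="linear")
        g = tertile_stratify(s)
        expected = np.where(s <= q1, "low", np.where(s <= q2, "mid", "high"))
        assert list(g.astype(str)) == list(expected)

    def test_boundary_ties_go_low(self):
        s = [1.0, 1.0, 1.0, 1.0, 5.0, 9.0]
        g = tertile_stratify(s)
        assert (g[:4].astype(str) == "low").all()


class TestHazardRatio:
    def test_two_group_recovery(self):
        cohort, groups = make_two_group_cohort(
            n_samples=600, hazard_ratio=2.0, seed=8
        )
        res = hazard_ratio(groups, cohort, reference="low")
        assert res.table.loc["high", "lower"] < 2.0 < res.table.loc["high", "upper"]
        assert res.table.loc["high", "hr"] == pytest.approx(2.0, rel=0.25)

    def test_null_groups_hr_near_one(self):
        cohort, groups = make_two_group_cohort(
            n_samples=800, hazard_ratio=1.0, seed=9
        )
        res = hazard_ratio(groups, cohort)
        assert res.table.loc["high", "hr"] == pytest.approx(1.0, abs=0.25)

    def test_group_without_events_rejected(self):
        c = cohort_from([1, 2, 3, 4], [1, 1, 0, 0])
        with pytest.raises(ValueError):
            hazard_ratio(["a", "a", "b", "b"], c, reference="a")


class TestMeta:
    def test_homogeneous_studies(self):
        m = meta_random_effects([0.6, 0.6], [0.05, 0.05])
        assert m.pooled_estimate == pytest.approx(0.6)
        assert m.tau2 == 0.0

    def test_hand_evaluated_dl_formulas(self):
        # w = 100 each; fixed pooled 0.6; Q = 100*(0.01+0.01) = 2
        # tau2 = (2-1)/(200 - 20000/200) = 0.01
        m = meta_random_effects([0.5, 0.7], [0.1, 0.1])
        assert m.q_statistic == pytest.approx(2.0)
        assert m.tau2 == pytest.approx(0.01)
        assert m.pooled_estimate == pytest.approx(0.6)

    def test_pooled_within_study_hull(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            est = rng.normal(0, 1, 4)
            se = rng.uniform(0.05, 0.5, 4)
            m = meta_random_effects(est, se)
            assert est.min() - 1e-12 <= m.pooled_estimate <= est.max() + 1e-12

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.meta_analysis import combine_effects

        est = np.array([0.2, 0.5, 0.35, 0.6])
        se = np.array([0.1, 0.15, 0.08, 0.2])
        m = meta_random_effects(est, se)
        res = combine_effects(est, se**2, method_re="dl")
        df = res.summary_frame()
        assert m.pooled_estimate == pytest.approx(
            df.loc["random effect", "eff"], abs=1e-10
        )
        assert m.tau2 == pytest.approx(res.tau2, abs=1e-10)

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            meta_random_effects([0.5], [0.1])


class TestFisherCombined:
    def test_all_ones(self):
        x, p = fisher_combined([1.0, 1.0, 1.0])
        assert x == 0.0 and p == 1.0

    def test_two_p05(self):
        x, p = fisher_combined([0.05, 0.05])
        assert x == pytest.approx(11.9829, abs=1e-4)
        # chi-square df 4 tail has closed form exp(-x/2)*(1 + x/2)
        assert p == pytest.approx(np.exp(-x / 2) * (1 + x / 2), abs=1e-12)
        assert p == pytest.approx(0.01745, abs=1e-4)

    def test_single_p_identity(self):
        _, p = fisher_combined([0.37])
        assert p == pytest.approx(0.37, abs=1e-12)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combined([0.0, 0.5])


class TestCompareScores:
    def test_identical_scores_tie(self):
        cohort, _ = make_two_group_cohort(n_samples=100, seed=10)
        s = pd.Series(
            np.random.default_rng(0).normal(size=100), index=cohort.data.index
        )
        out = compare_scores_meta(s, s.copy(), [cohort], B=100, seed=0)
        assert out["difference"] == 0.0 and out["p"] == 1.0

    def test_informative_vs_noise_score(self):
        rng = np.random.default_rng(11)
        cohorts, sa, sb = [], [], []
        for k in range(3):
            n = 200
            risk = rng.normal(size=n)
            t, e = simulate_survival(1.5 * risk, 0.2, 0.2, rng)
            c = cohort_from(t, e)
            cohorts.append(c)
            sa.append(pd.Series(risk, index=c.data.index))
            sb.append(pd.Series(rng.normal(size=n), index=c.data.index))
        out = compare_scores_meta(sa, sb, cohorts, B=150, seed=1)
        assert out["difference"] > 0
        assert out["p"] < 0.05
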