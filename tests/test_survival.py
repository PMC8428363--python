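"""Endpoint derivation and the survival/bootstrap statistics, each checked
against an independent oracle where one exists."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import ihc_autoscore as ia
from ihc_autoscore.survival import (Outcome, bca_ci,
                                    cindex_difference_test,
                                    concordance_index, cox_fit, derive_bcr,
                                    harrell_cindex, km_curve, logrank_test,
                                    pearson_r, roc_auc)


class TestDeriveBcr:
    def test_event_at_first_measurement_reaching_threshold(self):
        out = derive_bcr([1, 2, 3], [0.1, 0.2, 0.45])
        assert out == Outcome(time=3, event=True)

    def test_threshold_value_itself_is_an_event(self):
        out = derive_bcr([1], [0.4])
        assert out == Outcome(time=1, event=True)

    def test_censored_at_last_registration(self):
        out = derive_bcr([1, 2], [0.1, 0.2])
        assert out == Outcome(time=2, event=False)

    def test_unsorted_series_is_ordered_first(self):
        out = derive_bcr([3, 1, 2], [0.45, 0.1, 0.5])
        assert out == Outcome(time=2, event=True)

    def test_iso_dates_with_surgery_date(self):
        out = derive_bcr(["2011-01-01", "2012-01-01"], [0.1, 0.6],
                         surgery_date="2010-01-01")
        assert out.event and out.time == pytest.approx(2.0, abs=0.01)

    def test_no_postsurgery_psa_rejected(self):
        with pytest.raises(ValueError, match="follow-up"):
            derive_bcr([], [])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = km_curve(times, [True] * 5)
        tbl = res["all"]["table"]
        surv = dict(zip(tbl["event_at"], tbl["survival"]))
        for k, t in enumerate(times, start=1):
            assert surv[t] == pytest.approx(1 - k / 5)

    def test_all_censored_stays_flat_at_one(self):
        res = km_curve([1.0, 2.0, 3.0], [False, False, False])
        assert (res["all"]["table"]["survival"] == 1.0).all()

    def test_textbook_product_limit_values(self):
        # classic 6-subject example: events at 6, 6, 6; censor 6+; event 7;
        # censor 9+ -> S(6) = 1 - 3/6 = 0.5 ... wait at-risk 6 at t=6
        times = [6, 6, 6, 6, 7, 9]
        events = [1, 1, 1, 0, 1, 0]
        res = km_curve(times, [bool(e) for e in events])
        tbl = res["all"]["table"]
        surv = dict(zip(tbl["event_at"], tbl["survival"]))
        # hand product-limit: S(6) = (1 - 3/6) = 0.5; S(7) = 0.5*(1 - 1/2)
        assert surv[6] == pytest.approx(0.5)
        assert surv[7] == pytest.approx(0.25)

    def test_km_at_risk_accounting(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 60).round(2)
        e = rng.random(60) < 0.7
        tbl = km_curve(t, e)["all"]["table"]
        at_risk = tbl["at_risk"].to_numpy()
        removed = tbl["removed"].to_numpy()  # events + censored at each time
        assert (at_risk[1:] == at_risk[:-1] - removed[:-1]).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_curve([], [])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, True, False, True]
        chi2, p, df = logrank_test(t + t, e + e, [0] * 4 + [1] * 4)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_against_hand_accumulated_oe_table(self):
        """Small two-group case versus explicit observed-minus-expected
        accumulation of the Mantel-Cox statistic."""
        t = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1], dtype=bool)
        g = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        chi2, p, _ = logrank_test(t, e, g)
        # oracle: loop event times, accumulate O-E and hypergeometric var
        o_minus_e, var = 0.0, 0.0
        for ti in sorted(set(t[e])):
            at_risk = t >= ti
            n, n1 = at_risk.sum(), (at_risk & (g == 1)).sum()
            d = (e & (t == ti)).sum()
            d1 = (e & (t == ti) & (g == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e ** 2 / var
        assert chi2 == pytest.approx(expected_chi2, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1, 2], [True, True], [0, 0])

    def test_null_type_one_error_near_nominal(self):
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 300
        for _ in range(reps):
            t = rng.exponential(1, 60)
            e = rng.random(60) < 0.8
            g = rng.integers(0, 2, 60)
            if len(np.unique(g)) < 2:
                continue
            _, p, _ = logrank_test(t, e, g)
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) < 0.04


class TestCox:
    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(1)
        covered = 0
        reps = 60
        for r in range(reps):
            n = 300
            x = rng.integers(0, 2, n)
            t = rng.exponential(1, n)
            e = rng.random(n) < 0.8
            df = pd.DataFrame({"time": t, "event": e.astype(int), "x": x})
            res = cox_fit(df, "time", "event", ["x"])
            row = res.summary.iloc[0]
            covered += row.ci_low <= 1.0 <= row.ci_high
        assert covered / reps > 0.85

    def test_categorical_covariate_with_reference_level(self, small_cohort):
        df = small_cohort.copy()
        res = cox_fit(df, "time", "event", ["ploidy"],
                      categorical={"ploidy": "diploid"})
        names = set(res.summary["covariate"])
        assert names == {"ploidy[aneuploid]", "ploidy[tetraploid]"}
        chi2, dfree, p = res.group_tests["ploidy"]
        assert dfree == 2 and chi2 >= 0 and 0 <= p <= 1

    def test_univariable_cox_agrees_with_logrank_on_large_n(self):
        df = ia.generate_cohort(ia.CohortParams(n_patients=1500, seed=2))
        res = cox_fit(df, "time", "event", ["pten_low_true"])
        _, p_lr, _ = logrank_test(df.time, df.event.astype(bool),
                                  df.pten_low_true)
        p_cox = float(res.summary.iloc[0]["p"])
        # asymptotically equivalent tests: same conclusion, similar scale
        assert (p_cox < 0.05) == (p_lr < 0.05)
        if p_lr > 1e-12:
            assert abs(np.log10(p_cox) - np.log10(p_lr)) < 2

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"time": [1, 2, 3], "event": [0, 0, 0],
                           "x": [0, 1, 0]})
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, "time", "event", ["x"])


class TestConcordance:
    def test_reverse_ranked_times_give_one(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        e = np.ones(5, dtype=bool)
        assert concordance_index(t, e, -t) == 1.0

    def test_constant_score_gives_half(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.ones(3, dtype=bool)
        assert concordance_index(t, e, np.zeros(3)) == 0.5

    def test_matches_exhaustive_pairwise_oracle_with_censoring(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(2, 50)
        e = rng.random(50) < 0.6
        r = rng.normal(0, 1, 50)
        got = concordance_index(t, e, r)
        conc = disc = ties = 0
        for i in range(50):
            for j in range(50):
                if i == j:
                    continue
                comparable = (t[i] < t[j] and e[i]) or \
                             (t[i] == t[j] and e[i] and not e[j])
                if not comparable:
                    continue
                if r[i] > r[j]:
                    conc += 1
                elif r[i] < r[j]:
                    disc += 1
                else:
                    ties += 1
        expected = (conc + 0.5 * ties) / (conc + disc + ties)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_lifelines_on_tie_free_data(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(11)
        t = rng.exponential(2, 80)      # continuous: no tied times
        e = rng.random(80) < 0.7
        r = rng.normal(0, 1, 80)
        # lifelines measures concordance of *predicted survival time*
        assert concordance_index(t, e, r) == pytest.approx(
            ll_cindex(t, -r, e), abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1.0, 2.0], [False, False], [0.1, 0.2])

    def test_cindex_equals_auc_without_censoring_binary_time(self):
        """With every subject observed and risk scores against event-by-time
        truth, Harrell's c on 'time' equals ROC AUC of the scores."""
        rng = np.random.default_rng(5)
        n = 60
        score = rng.normal(0, 1, n)
        # event occurs early for high scores
        t = np.where(score + rng.normal(0, 0.5, n) > 0, 1.0, 2.0)
        e = np.ones(n, dtype=bool)
        auc = roc_auc((t == 1.0).astype(int), score, with_ci=False).auc
        assert concordance_index(t, e, score) == pytest.approx(auc, abs=1e-12)


class TestBca:
    def test_symmetric_data_close_to_percentile_interval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 120)
        iv = bca_ci(lambda a: np.mean(a, axis=-1), x, n_bootstraps=4000,
                    seed=1, vectorized=True)
        rng2 = np.random.default_rng(1)
        idx = rng2.integers(0, 120, size=(4000, 120))
        boot = x[idx].mean(axis=1)
        lo, hi = np.quantile(boot, [0.025, 0.975])
        assert iv.low == pytest.approx(lo, abs=0.03)
        assert iv.high == pytest.approx(hi, abs=0.03)

    def test_matches_scipy_bca_endpoints(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(1, 60)  # skewed: BCa differs from percentile
        iv = bca_ci(lambda a: np.mean(a, axis=-1), x, n_bootstraps=9999,
                    seed=2, vectorized=True)
        res = sps.bootstrap((x,), np.mean, n_resamples=9999, method="BCa",
                            random_state=2)
        assert iv.low == pytest.approx(res.confidence_interval.low, abs=0.02)
        assert iv.high == pytest.approx(res.confidence_interval.high, abs=0.02)

    def test_interval_stabilizes_as_bootstraps_grow(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 80)
        stat = lambda a: np.mean(a, axis=-1)
        small = [bca_ci(stat, x, n_bootstraps=200, seed=s, vectorized=True)
                 for s in range(8)]
        large = [bca_ci(stat, x, n_bootstraps=8000, seed=s, vectorized=True)
                 for s in range(8)]
        spread = lambda ivs: np.std([iv.low for iv in ivs])
        assert spread(large) < spread(small)

    def test_degenerate_distribution_collapses_flagged(self):
        x = np.ones(30)
        iv = bca_ci(lambda a: np.mean(a, axis=-1), x, n_bootstraps=200,
                    seed=0, vectorized=True)
        assert iv.degenerate and iv.low == iv.high == 1.0

    def test_too_few_bootstraps_rejected(self):
        with pytest.raises(ValueError, match="at least 100"):
            bca_ci(np.mean, np.arange(10.0), n_bootstraps=50)


class TestDifferenceTest:
    def test_identical_scores_delta_zero_p_one(self, small_cohort):
        df = small_cohort
        res = cindex_difference_test(df.time, df.event.astype(bool),
                                     df.capra_s.astype(float),
                                     df.capra_s.astype(float),
                                     n_bootstraps=200, seed=0)
        assert res.delta == 0.0 and res.p == 1.0

    def test_p_consistent_with_95_interval(self, small_cohort):
        """p < 0.05 exactly when the 95% BCa interval excludes zero."""
        df = small_cohort
        rng = np.random.default_rng(9)
        for trial in range(4):
            a = df.capra_s.astype(float) + rng.normal(0, 0.5, len(df))
            b = rng.permutation(a.to_numpy())
            res = cindex_difference_test(df.time, df.event.astype(bool),
                                         a, b, n_bootstraps=600,
                                         seed=trial)
            excludes = res.ci_low > 0 or res.ci_high < 0
            assert (res.p < 0.05) == excludes

    def test_informative_vs_random_score_significant(self):
        df = ia.generate_cohort(ia.CohortParams(n_patients=500, seed=21))
        rng = np.random.default_rng(1)
        informative = 1.0 - df.pten_score_true  # higher risk, shorter time
        noise = rng.normal(0, 1, len(df))
        res = cindex_difference_test(df.time, df.event.astype(bool),
                                     informative, noise,
                                     n_bootstraps=1000, seed=2)
        assert res.delta > 0 and res.p < 0.05


class TestAucAndPearson:
    def test_perfect_separation_gives_one(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        assert roc_auc(y, s, with_ci=False).auc == 1.0

    def test_auc_equals_normalized_mann_whitney_u(self):
        y = np.array([0, 1, 0, 1, 1, 0, 0, 1, 1, 0])
        s = np.array([0.2, 0.9, 0.4, 0.55, 0.7, 0.3, 0.65, 0.8, 0.5, 0.1])
        u = sps.mannwhitneyu(s[y == 1], s[y == 0],
                             alternative="two-sided").statistic
        expected = u / ((y == 1).sum() * (y == 0).sum())
        assert roc_auc(y, s, with_ci=False).auc == pytest.approx(expected,
                                                                 abs=1e-12)

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 4000)
        s = rng.normal(0, 1, 4000)
        assert roc_auc(y, s, with_ci=False).auc == pytest.approx(0.5,
                                                                 abs=0.05)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_pearson_exact_linear(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_pearson_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([2.0, 3.5, 3.0, 6.0, 8.0])
        r, ci = pearson_r(x, y)
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std() * y.std())
        assert r == pytest.approx(expected, abs=1e-12)
        assert ci[0] < r < ci[1]

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestHarrellWithCi:
    def test_ci_brackets_estimate_and_stays_in_unit_interval(self,
                                                             small_cohort):
        df = small_cohort
        res = harrell_cindex(df.time, df.event.astype(bool),
                             1.0 - df.pten_score_true,
                             n_bootstraps=500, seed=1)
        assert 0.0 <= res.ci_low <= res.cindex <= res.ci_high <= 1.0
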