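"""Self-implemented survival and rank statistics against hand results and
independent oracles (lifelines, scipy, sklearn, brute-force enumeration)."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mirascore.survstats import (
    SurvivalRecord,
    km_estimate,
    logrank_test,
    mann_whitney_u,
    roc_auc,
    spearman_one_sided,
)
from tests.conftest import make_records


class TestKaplanMeier:
    def test_hand_example(self, km_hand_example):
        curve = km_estimate(km_hand_example)
        assert list(curve.event_times) == [1.0, 2.0]
        assert curve.survival == pytest.approx([2 / 3, 1 / 3])
        assert curve.survival_at(3.0) == pytest.approx(1 / 3)
        assert curve.survival_at(0.5) == 1.0

    def test_all_censored_stays_at_one(self):
        curve = km_estimate(make_records([5, 10, 15], [0, 0, 0]))
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_single_event_drops_to_zero(self):
        curve = km_estimate(make_records([7], [1]))
        assert curve.survival_at(7.0) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])

    def test_censored_tied_with_event_stays_at_risk(self):
        # at t=5: 3 at risk (the patient censored at 5 included), 1 event
        curve = km_estimate(make_records([5, 5, 8], [1, 0, 1]))
        assert curve.at_risk[0] == 3
        assert curve.survival_at(5.0) == pytest.approx(2 / 3)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(50, 200).round(1) + 0.1
        e = (rng.random(200) < 0.6).astype(int)
        curve = km_estimate(make_records(t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        for et, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(float(kmf.predict(et)), abs=1e-10)

    def test_converges_to_exponential_truth(self):
        # sup-norm deviation from the generating exponential curve at n = 5000
        rng = np.random.default_rng(99)
        lam = 1 / 40
        t_true = rng.exponential(1 / lam, 5000)
        c = rng.uniform(10, 200, 5000)
        t = np.minimum(t_true, c)
        e = (t_true <= c).astype(int)
        curve = km_estimate(make_records(t, e))
        inside = curve.event_times <= 150  # where the at-risk set stays large
        dev = np.abs(curve.survival[inside] - np.exp(-lam * curve.event_times[inside]))
        assert dev.max() < 0.02


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        g = make_records([3, 5, 9, 12], [1, 0, 1, 1])
        res = logrank_test([g, list(g)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0
        assert res.df == 1

    def test_label_symmetry(self, rng):
        a = make_records(rng.exponential(30, 10) + 1, rng.integers(0, 2, 10), "a")
        b = make_records(rng.exponential(60, 12) + 1, rng.integers(0, 2, 12), "b")
        r1, r2 = logrank_test([a, b]), logrank_test([b, a])
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_no_events_anywhere_is_null_result(self):
        a = make_records([5, 6], [0, 0], "a")
        b = make_records([7, 8], [0, 0], "b")
        res = logrank_test([a, b])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_group_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        ta, ea = rng.exponential(30, 40) + 1, (rng.random(40) < 0.7).astype(int)
        tb, eb = rng.exponential(60, 35) + 1, (rng.random(35) < 0.7).astype(int)
        res = logrank_test([make_records(ta, ea, "a"), make_records(tb, eb, "b")])
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-6)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-6)

    def test_three_group_matches_lifelines(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        times, events, labels = [], [], []
        for k, (scale, n) in enumerate([(30, 20), (50, 25), (80, 22)]):
            times.append(rng.exponential(scale, n) + 1)
            events.append((rng.random(n) < 0.7).astype(int))
            labels.append(np.full(n, k))
        groups = [make_records(t, e, str(k)) for k, (t, e) in enumerate(zip(times, events))]
        res = logrank_test(groups)
        ref = multivariate_logrank_test(
            np.concatenate(times), np.concatenate(labels), np.concatenate(events)
        )
        assert res.df == 2
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-6)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-6)

    def test_needs_two_nonempty_groups(self):
        g = make_records([1], [1])
        with pytest.raises(ValueError):
            logrank_test([g])
        with pytest.raises(ValueError):
            logrank_test([g, []])


class TestSpearmanOneSided:
    def test_perfect_anticorrelation_exact_p(self):
        res = spearman_one_sided([1, 2, 3, 4, 5], [10, 8, 6, 4, 2], "negative")
        assert res.statistic == pytest.approx(-1.0)
        assert res.p_value == pytest.approx(1 / 120)

    def test_perfect_positive_correlation(self):
        res = spearman_one_sided([1, 2, 3, 4, 5], [2, 4, 5, 7, 9], "positive")
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 120)

    def test_wrong_direction_p_near_one(self):
        res = spearman_one_sided([1, 2, 3, 4, 5], [2, 4, 5, 7, 9], "negative")
        assert res.p_value >= 0.99

    def test_exact_and_approx_agree_at_n9(self, rng):
        for _ in range(10):
            x = rng.permutation(9).astype(float)
            y = rng.permutation(9).astype(float)
            exact = spearman_one_sided(x, y, "negative", method="exact")
            approx = spearman_one_sided(x, y, "negative", method="approx")
            assert abs(exact.p_value - approx.p_value) < 0.01

    def test_rho_matches_scipy_and_p_tracks_t_tail(self, rng):
        # scipy's p is the plain t tail; ours adds a lattice continuity
        # correction, so compare rho exactly and p within the correction size
        for _ in range(5):
            x = rng.permutation(12).astype(float)
            y = rng.permutation(12).astype(float)
            res = spearman_one_sided(x, y, "negative", method="approx")
            ref = stats.spearmanr(x, y, alternative="less")
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue, abs=0.01)

    def test_ties_fall_back_to_approximation(self):
        res = spearman_one_sided([1, 1, 2, 3, 4], [5, 4, 3, 2, 1], "negative")
        assert res.statistic < 0 and 0 < res.p_value < 0.2

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_one_sided([1, 1, 1, 1], [1, 2, 3, 4])


class TestMannWhitney:
    def test_complete_separation_small_n(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 orderings as extreme

    def test_identical_multisets_give_midpoint_u(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(8.0)  # n_x*n_y/2

    def test_swap_reflects_u_same_p(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=5)
        a, b = mann_whitney_u(x, y), mann_whitney_u(y, x)
        assert a.statistic == pytest.approx(8 * 5 - b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_exact_matches_scipy(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        res = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_approx_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 6, 30).astype(float)
        y = rng.integers(1, 7, 25).astype(float)
        res = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0
        assert res.tpr[0] == 0.0 and res.tpr[-1] == 1.0
        assert res.fpr[0] == 0.0 and res.fpr[-1] == 1.0

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(size=400)
        labels = (rng.random(400) < 0.3).astype(int)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=60).round(1)  # rounding forces ties
        labels = (rng.random(60) < 0.4).astype(int)
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = (rng.random(50) < 0.4).astype(int)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(scores), labels)
        assert a.auc == pytest.approx(b.auc)
        assert a.p_value == pytest.approx(b.p_value)

    def test_permutation_p_agrees_with_analytic(self, rng):
        scores = np.concatenate([rng.normal(0.8, 1, 15), rng.normal(0, 1, 25)])
        labels = np.array([1] * 15 + [0] * 25)
        analytic = roc_auc(scores, labels)
        permuted = roc_auc(scores, labels, rng=np.random.default_rng(0), n_permutations=4000)
        assert permuted.p_value == pytest.approx(analytic.p_value, abs=0.02)
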