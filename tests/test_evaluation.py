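import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathsurv.evaluation import (
    chi_square_association,
    km_estimate,
    roc_auc,
    weighted_logrank_test,
)


def gehan_statistic(time, event, in_a):
    """Hand implementation of the Gehan-Wilcoxon weighted log-rank chi-square."""
    U = V = 0.0
    for u in np.unique(time[event == 1]):
        at = time >= u
        n, n1 = at.sum(), (at & in_a).sum()
        d = ((time == u) & (event == 1)).sum()
        d1 = ((time == u) & (event == 1) & in_a).sum()
        w = n
        U += w * (d1 - d * n1 / n)
        if n > 1:
            V += w * w * d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return U * U / V if V > 0 else 0.0


class TestKaplanMeier:
    def test_hand_product_limit_values(self):
        # times 1, 2+, 3, 4+, 5 with events at 1, 3, 5
        km = km_estimate((np.array([1.0, 2, 3, 4, 5]), np.array([1, 0, 1, 0, 1])))
        assert km.at(1.0) == pytest.approx(0.8)
        assert km.at(3.5) == pytest.approx(0.8 * (2 / 3))
        assert km.at(3.5) == pytest.approx(0.5333, abs=1e-4)
        assert km.at(5.0) == pytest.approx(0.0)

    def test_no_events_flat_at_one(self):
        km = km_estimate((np.array([1.0, 2, 3]), np.array([0, 0, 0])))
        assert km.at(2.5) == 1.0
        assert len(km.event_times) == 0

    def test_all_events_at_single_time(self):
        km = km_estimate((np.array([2.0, 2, 2]), np.array([1, 1, 1])))
        assert km.at(1.9) == 1.0
        assert km.at(2.0) == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2, 40)
        km = km_estimate((t, np.ones(40, int)))
        for u in [0.5, 1.0, 2.0, 4.0]:
            assert km.at(u) == pytest.approx((t > u).mean(), abs=1e-12)


class TestWeightedLogrank:
    def test_identical_groups_give_null(self):
        t = np.array([1.0, 2, 3, 4])
        e = np.array([1, 0, 1, 1])
        res = weighted_logrank_test((t, e), (t, e))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_matches_hand_gehan_on_toy(self):
        ta, ea = np.array([1.0, 3, 5]), np.array([1, 1, 1])
        tb, eb = np.array([2.0, 4, 6]), np.array([0, 1, 1])
        res = weighted_logrank_test((ta, ea), (tb, eb))
        expected = gehan_statistic(
            np.concatenate([ta, tb]), np.concatenate([ea, eb]),
            np.array([True] * 3 + [False] * 3),
        )
        assert res.statistic == pytest.approx(expected, abs=1e-10)

    def test_p_value_calibrated_against_permutation_oracle(self):
        # moderate two-group toy: asymptotic p must sit within Monte-Carlo
        # error of a 20,000-draw permutation null of the same statistic
        rng = np.random.default_rng(42)
        n = 50
        time = rng.exponential(3, n)
        event = (rng.random(n) < 0.8).astype(int)
        in_a = np.zeros(n, bool)
        in_a[rng.choice(n, 25, replace=False)] = True
        time[in_a] *= 1.35
        res = weighted_logrank_test((time[in_a], event[in_a]), (time[~in_a], event[~in_a]))
        obs = gehan_statistic(time, event, in_a)
        draws = 20_000
        count = 0
        for _ in range(draws):
            perm = np.zeros(n, bool)
            perm[rng.choice(n, 25, replace=False)] = True
            if gehan_statistic(time, event, perm) >= obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / draws, abs=0.02)

    def test_time_scaling_invariance(self):
        rng = np.random.default_rng(3)
        ta, tb = rng.exponential(1, 20), rng.exponential(2, 20)
        ea, eb = np.ones(20, int), np.ones(20, int)
        r1 = weighted_logrank_test((ta, ea), (tb, eb))
        r2 = weighted_logrank_test((7.3 * ta, ea), (7.3 * tb, eb))
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-10)

    def test_no_events_warns_p_one(self):
        with pytest.warns(UserWarning):
            res = weighted_logrank_test(
                (np.array([1.0, 2]), np.array([0, 0])), (np.array([3.0]), np.array([0]))
            )
        assert res.p_value == 1.0

    def test_null_type_one_error_near_nominal(self):
        # both groups drawn from one exponential law: the p-value should be
        # approximately uniform, so rejections at 0.05 stay near 5%
        rng = np.random.default_rng(2024)
        n, reps = 200, 500
        rejections = 0
        for _ in range(reps):
            t = rng.exponential(2, n)
            c = rng.uniform(0, 6, n)
            time, event = np.minimum(t, c), (t <= c).astype(int)
            half = np.zeros(n, bool)
            half[rng.choice(n, n // 2, replace=False)] = True
            p = weighted_logrank_test((time[half], event[half]), (time[~half], event[~half])).p_value
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestRocAuc:
    def test_perfectly_ordered_scores(self):
        res = roc_auc(np.arange(10.0), np.array([0] * 5 + [1] * 5))
        assert res.auc == 1.0

    def test_inverted_labels_give_zero(self):
        res = roc_auc(np.arange(10.0), np.array([1] * 5 + [0] * 5))
        assert res.auc == 0.0

    def test_equals_all_pairs_concordance_exactly(self):
        rng = np.random.default_rng(11)
        scores = rng.choice(np.linspace(0, 1, 8), size=20)  # forces ties
        labels = rng.integers(0, 2, 20)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        res = roc_auc(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        num = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert res.auc == num / (len(pos) * len(neg))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry_under_score_negation(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=15).round(1)
        labels = rng.integers(0, 2, 15)
        if len(np.unique(labels)) < 2:
            labels[:2] = [0, 1]
        assert roc_auc(scores, labels).auc + roc_auc(-scores, labels).auc == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4, int))


class TestChiSquare:
    def test_independent_table_is_null(self):
        groups = ["a"] * 50 + ["b"] * 50
        outcome = ([0] * 25 + [1] * 25) * 2
        stat, p = chi_square_association(groups, outcome)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_expected_count_formula(self):
        # table [[10,20],[20,10]]: n(ad-bc)^2 / (r1 r2 c1 c2)
        groups = ["a"] * 30 + ["b"] * 30
        outcome = [0] * 10 + [1] * 20 + [0] * 20 + [1] * 10
        stat, _ = chi_square_association(groups, outcome)
        n, a, b, c, d = 60, 10, 20, 20, 10
        expected = n * (a * d - b * c) ** 2 / (30 * 30 * 30 * 30)
        assert stat == pytest.approx(expected, abs=1e-10)
        assert stat == pytest.approx(6.6667, abs=1e-3)

    def test_row_swap_invariance(self):
        groups = ["a"] * 30 + ["b"] * 30
        outcome = [0] * 10 + [1] * 20 + [0] * 18 + [1] * 12
        s1, _ = chi_square_association(groups, outcome)
        swapped = ["b" if g == "a" else "a" for g in groups]
        s2, _ = chi_square_association(swapped, outcome)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_association(["a"] * 4, [0, 1, 0, 1])
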