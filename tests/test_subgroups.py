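"""Subgroup comparisons: rank tests, exact call-rate tests, age models."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from methylnode.classification import BENIGN, MALIGNANT
from methylnode.errors import DegenerateInputError, InvalidArgumentError
from methylnode.subgroups import (
    age_trend,
    call_rate_table,
    compare_groups,
    misclassification_vs_age,
)


class TestCompareGroups:
    def test_identical_groups_null_case(self):
        values = [1.0, 2.0, 3.0, 4.0] * 2
        groups = ["a"] * 4 + ["b"] * 4
        res = compare_groups(values, groups)
        assert res.p_value > 0.9

    def test_exact_p_matches_full_enumeration(self):
        """4-vs-4 tie-free data: p equals enumeration over all C(8,4) splits."""
        a = [1.0, 5.0, 7.0, 11.0]
        b = [2.0, 3.0, 9.0, 4.0]
        res = compare_groups(a + b, ["a"] * 4 + ["b"] * 4)
        pooled = np.array(a + b)

        def u_stat(idx_a):
            xa = pooled[list(idx_a)]
            xb = pooled[[i for i in range(8) if i not in idx_a]]
            return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in xa for y in xb)

        u_obs = u_stat(range(4))
        null = [u_stat(c) for c in itertools.combinations(range(8), 4)]
        cdf = np.mean([u <= u_obs for u in null])
        sf = np.mean([u >= u_obs for u in null])
        p_exact = min(1.0, 2 * min(cdf, sf))
        assert res.test == "mann-whitney"
        assert res.p_value == pytest.approx(p_exact, abs=1e-12)

    def test_study_like_separation_is_highly_significant(self, demo_study):
        meta = demo_study["cohort"].metadata
        from methylnode.synthetic import percent_level_draw

        rng = np.random.default_rng(9)
        cm_mal, cm_ben = percent_level_draw(demo_study["config"], 100, 100, rng)
        res = compare_groups(
            np.concatenate([cm_mal, cm_ben]), ["m"] * 100 + ["b"] * 100
        )
        assert res.p_value < 1e-4
        assert len(meta) == 230  # cohort fixture sanity

    def test_three_groups_use_kruskal_wallis(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=30)
        groups = ["a", "b", "c"] * 10
        res = compare_groups(values, groups)
        expected = stats.kruskal(values[0::3], values[1::3], values[2::3])
        assert res.test == "kruskal-wallis"
        assert res.p_value == pytest.approx(expected.pvalue)

    def test_two_group_kruskal_agrees_with_mann_whitney(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)])
        groups = ["a"] * 30 + ["b"] * 30
        res = compare_groups(values, groups)
        kw = stats.kruskal(values[:30], values[30:])
        assert res.p_value == pytest.approx(kw.pvalue, rel=0.05)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=20)
        groups = np.array(["a"] * 10 + ["b"] * 10)
        res = compare_groups(values, groups)
        perm = rng.permutation(20)
        res_perm = compare_groups(values[perm], groups[perm])
        assert res.p_value == pytest.approx(res_perm.p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compare_groups([1.0, 2.0], ["a", "a"])


def exact_2xk_fisher(table):
    """Enumeration oracle: two-sided Fisher p for a small 2xk table."""
    table = np.asarray(table)
    col = table.sum(axis=0)
    row0 = table.sum(axis=1)[0]
    n = table.sum()

    def log_prob(first_row):
        lp = -(gammaln(n + 1) - gammaln(row0 + 1) - gammaln(n - row0 + 1))
        for c, a in zip(col, first_row):
            lp += gammaln(c + 1) - gammaln(a + 1) - gammaln(c - a + 1)
        return lp

    obs = log_prob(table[0])
    ranges = [range(0, c + 1) for c in col]
    p = 0.0
    for combo in itertools.product(*ranges):
        if sum(combo) != row0:
            continue
        lp = log_prob(combo)
        if lp <= obs + 1e-9:
            p += np.exp(lp)
    return p


class TestCallRateTable:
    def test_identical_rates_tiny_n(self):
        calls = [MALIGNANT, BENIGN, MALIGNANT, BENIGN]
        res = call_rate_table(calls, ["a", "a", "b", "b"])
        assert res.p_value == 1.0

    def test_2x2_matches_hand_hypergeometric(self):
        # table (3,1;1,3): two-sided p = 34/70
        calls = [MALIGNANT] * 3 + [BENIGN] + [MALIGNANT] + [BENIGN] * 3
        subtype = ["a"] * 4 + ["b"] * 4
        res = call_rate_table(calls, subtype)
        assert res.method == "fisher-exact"
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)

    def test_monte_carlo_matches_enumeration_on_2x3(self):
        calls = (
            [MALIGNANT] * 5 + [BENIGN] * 2
            + [MALIGNANT] * 2 + [BENIGN] * 5
            + [MALIGNANT] * 3 + [BENIGN] * 3
        )
        subtype = ["a"] * 7 + ["b"] * 7 + ["c"] * 6
        res = call_rate_table(calls, subtype, n_mc=100_000, seed=0)
        expected = exact_2xk_fisher(res.table.to_numpy())
        assert res.method == "fisher-monte-carlo"
        assert res.p_value == pytest.approx(expected, abs=0.01)

    def test_equal_positivity_null_is_nonsignificant(self):
        rng = np.random.default_rng(3)
        subtype = rng.choice(["a", "b", "c", "d"], size=200)
        calls = np.where(rng.random(200) < 0.8, MALIGNANT, BENIGN)
        res = call_rate_table(calls, subtype, n_mc=20_000, seed=1)
        assert res.p_value > 0.05

    def test_empty_level_dropped_with_warning(self):
        calls = [MALIGNANT, BENIGN, MALIGNANT, BENIGN]
        subtype = ["a", "a", "b", "b"]
        with pytest.warns(UserWarning, match="empty"):
            res = call_rate_table(calls, subtype, levels=["a", "b", "c"])
        assert res.method == "fisher-exact"
        assert res.p_value == 1.0


class TestAgeTrend:
    def test_flat_cm_has_zero_slope(self):
        res = age_trend([5.0] * 10, list(range(40, 50)))
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_two_points_exact_line_with_undefined_p(self):
        res = age_trend([1.0, 3.0], [40.0, 50.0])
        assert res.slope == pytest.approx(0.2)
        assert res.p_value is None

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        age = rng.uniform(30, 80, size=10)
        cm = 0.05 * age + rng.normal(0, 1, size=10)
        res = age_trend(cm, age)
        x = np.vstack([np.ones(10), age]).T
        beta = np.linalg.solve(x.T @ x, x.T @ cm)
        assert res.intercept == pytest.approx(beta[0], abs=1e-9)
        assert res.slope == pytest.approx(beta[1], abs=1e-9)
        lr = stats.linregress(age, cm)
        assert res.p_value == pytest.approx(lr.pvalue, abs=1e-9)
        assert res.r == pytest.approx(lr.rvalue, abs=1e-12)

    def test_constant_age_undefined(self):
        with pytest.raises(DegenerateInputError):
            age_trend([1.0, 2.0, 3.0], [50.0, 50.0, 50.0])


def irls_logistic(y, x, n_iter=50):
    """Independent IRLS oracle for logistic regression with intercept."""
    X = np.vstack([np.ones(len(x)), x]).T
    beta = np.zeros(2)
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * z))
    return beta


class TestMisclassificationVsAge:
    def test_logistic_fit_matches_irls_oracle(self):
        age = np.array([35, 40, 45, 48, 50, 52, 55, 58, 62, 66, 70, 75], dtype=float)
        cm = np.array([1, 2, 9, 1, 10, 2, 12, 1, 14, 2, 15, 16], dtype=float)
        truth = [BENIGN] * 12
        # add malignant samples so both classes are present but only the
        # benign false-positive fit is of interest
        age_full = np.concatenate([age, [50.0, 60.0]])
        cm_full = np.concatenate([cm, [200.0, 250.0]])
        truth_full = truth + [MALIGNANT, MALIGNANT]
        out = misclassification_vs_age(cm_full, age_full, truth_full, thresholds=[8.5])
        row = out[(out.error == "false_positive")].iloc[0]
        y = (cm > 8.5).astype(float)
        beta = irls_logistic(y, age)
        assert row.converged
        assert row.age_coef == pytest.approx(beta[1], abs=1e-6)

    def test_age_unrelated_misclassification_recovers_null(self):
        rng = np.random.default_rng(5)
        n = 400
        age = rng.uniform(30, 80, n)
        truth = np.where(rng.random(n) < 0.5, MALIGNANT, BENIGN)
        cm = np.where(truth == MALIGNANT, rng.gamma(5, 30, n), rng.exponential(2, n))
        out = misclassification_vs_age(cm, age, truth, thresholds=[2.0, 8.5, 20.0])
        fitted = out[out.converged]
        assert len(fitted) > 0
        assert np.all(np.abs(fitted.age_coef) < 0.1)

    def test_age_dependent_benign_cm_gives_positive_low_threshold_coef(self):
        """Benign CM rising with age: older benign patients are misclassified
        at low thresholds, and the effect fades at high thresholds."""
        rng = np.random.default_rng(6)
        n = 300
        age = rng.uniform(30, 80, n)
        benign_cm = rng.exponential(0.5 + 0.09 * (age - 30), n)
        mal_age = rng.uniform(30, 80, 100)
        mal_cm = rng.gamma(5, 40, 100)
        cm = np.concatenate([benign_cm, mal_cm])
        ages = np.concatenate([age, mal_age])
        truth = [BENIGN] * n + [MALIGNANT] * 100
        out = misclassification_vs_age(cm, ages, truth, thresholds=[2.0, 30.0])
        fp = out[out.error == "false_positive"].set_index("threshold")
        assert fp.loc[2.0, "age_coef"] > 0
        assert fp.loc[2.0, "p_value"] < 0.05
        low, high = fp.loc[2.0, "age_coef"], fp.loc[30.0, "age_coef"]
        assert (not fp.loc[30.0, "converged"]) or high < low

    def test_single_class_truth_rejected(self):
        with pytest.raises(DegenerateInputError):
            misclassification_vs_age([1.0, 2.0], [50, 60], [BENIGN, BENIGN], [8.5])
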