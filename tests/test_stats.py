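import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.special import comb

from octmech.stats import (auc_band, chi_square_2x2, delong_test,
                           fisher_exact_2x2, icc_oneway,
                           logistic_combination, paired_t, roc_auc,
                           two_sample_t, youden_cutoff)


# --------------------------------------------------------------------------
# independent oracles

def auc_pair_counting(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def fisher_two_sided_enumeration(a, b, c, d):
    """Sum hypergeometric P(table) over tables with P <= P(observed)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def youden_exhaustive(scores, labels, orientation_sign):
    s = orientation_sign * np.asarray(scores, float)
    uniq = np.unique(s)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2,
                            [uniq[-1] + 1]])
    pos = s[np.asarray(labels) == 1]
    neg = s[np.asarray(labels) == 0]
    best = -np.inf
    for t in cands:
        j = (pos >= t).mean() + (neg < t).mean() - 1
        best = max(best, j)
    return best


# --------------------------------------------------------------------------

class TestTwoSampleT:
    def test_printed_group_summaries(self):
        # minimal cap thickness 97+/-15 vs 49+/-10, n=10 each
        t, df, p = two_sample_t((97, 15, 10), (49, 10, 10))
        assert t == pytest.approx(8.42, abs=0.01)
        assert p < 0.001
        # maximal plaque stress 399+/-233 vs 90+/-95: p rounds to 0.001
        t, df, p = two_sample_t((399, 233, 10), (90, 95, 10))
        assert round(p, 3) == 0.001
        # peak cap stress 174+/-67 vs 52+/-42
        assert two_sample_t((174, 67, 10), (52, 42, 10))[2] < 0.001

    def test_matches_scipy_on_raw_samples(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 2, 17)
        t, df, p = two_sample_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        t, df, p = two_sample_t(a, b, pooled=False)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert p == pytest.approx(ref.pvalue)

    def test_degenerate_variance(self):
        assert two_sample_t(([1, 1, 1]), ([1, 1, 1]))[2] == 1.0
        with pytest.raises(ValueError):
            two_sample_t([1, 1], [2, 2])


class TestPairedT:
    def test_zero_differences_p_one(self):
        assert paired_t([0.0, 0.0, 0.0])[2] == 1.0

    def test_constant_nonzero_differences_degenerate(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 1.0, 1.0, 1.0])

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.3, 1, 15)
        t, df, p = paired_t(d)
        ref = sps.ttest_1samp(d, 0.0)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestFisherExact:
    def test_printed_tables(self):
        # thin-capped fibroatheroma 7/10 vs 0/10 and male sex 8/10 vs 8/10
        assert round(fisher_exact_2x2(7, 3, 0, 10), 3) == 0.003
        assert round(fisher_exact_2x2(8, 2, 8, 2), 3) == 1.000

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12), st.integers(0, 12))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_two_sided_enumeration(a, b, c, d), rel=1e-8)

    def test_table_family_probabilities_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            r1, r2, c1 = rng.integers(1, 30, 3)
            n = r1 + r2
            c1 = int(min(c1, n))
            total = sum(comb(r1, x, exact=True)
                        * comb(r2, c1 - x, exact=True)
                        for x in range(max(0, c1 - r2), min(r1, c1) + 1))
            assert total == comb(n, c1, exact=True)

    def test_all_zero_table(self):
        assert fisher_exact_2x2(0, 0, 0, 0) == 1.0


class TestChiSquare:
    @pytest.mark.parametrize("table,p", [
        ((4, 6, 6, 4), 0.371),    # macrophage presence
        ((10, 0, 9, 1), 0.305),   # hypertension
        ((3, 7, 4, 6), 0.639),    # nicotine use
    ])
    def test_printed_categorical_p_values(self, table, p):
        assert round(chi_square_2x2(*table)[1], 3) == p

    def test_symmetric_table_is_null(self):
        chi2, p = chi_square_2x2(5, 5, 5, 5)
        assert chi2 == 0.0 and p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 5)


class TestRoc:
    def test_perfect_separation(self):
        c = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert c.auc == 1.0

    def test_tie_handling_worked_example(self):
        assert roc_auc([1, 2, 2, 3], [0, 0, 1, 1]).auc == pytest.approx(0.875)

    def test_matches_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(4, 50))
            scores = rng.integers(0, 10, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            c = roc_auc(scores, labels, orientation="higher")
            assert c.auc == pytest.approx(
                auc_pair_counting(scores, labels), abs=1e-12)

    def test_auto_orientation_flips_low_is_positive(self):
        # thin caps (low values) mark the positive class
        fct = [60, 50, 45, 100, 110, 95]
        labels = [1, 1, 1, 0, 0, 0]
        c = roc_auc(fct, labels)
        assert c.orientation == -1
        assert c.auc == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        labels[0], labels[1] = 0, 1
        assert roc_auc(np.exp(s), labels).auc == pytest.approx(
            roc_auc(s, labels).auc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestYouden:
    def test_full_separation_midpoint(self):
        c = roc_auc([100, 140, 160, 200], [0, 0, 1, 1])
        cutoff, sens, spec = youden_cutoff(c)
        assert cutoff == pytest.approx(150.0)
        assert sens == 1.0 and spec == 1.0

    def test_equal_scores_degenerate(self):
        c = roc_auc([5, 5, 5, 5], [0, 1, 0, 1], orientation="higher")
        cutoff, sens, spec = youden_cutoff(c)
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = int(rng.integers(4, 50))
            scores = rng.normal(size=n).round(1)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            c = roc_auc(scores, labels, orientation="higher")
            cutoff, sens, spec = youden_cutoff(c)
            assert sens + spec - 1 == pytest.approx(
                youden_exhaustive(scores, labels, 1), abs=1e-12)


class TestAucBand:
    @pytest.mark.parametrize("auc,band", [
        (0.940, "excellent"), (0.950, "excellent"), (0.870, "very good"),
        (0.900, "excellent"), (0.630, "sufficient"), (0.75, "good"),
        (0.55, "not sufficient")])
    def test_published_labels_reproduced(self, auc, band):
        assert auc_band(auc) == band

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            auc_band(1.2)


class TestDeLong:
    def test_identical_scores_null(self):
        s = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        labels = [0, 0, 0, 1, 1, 1]
        auc_a, auc_b, z, p = delong_test(s, s, labels)
        assert z == 0.0 and p == 1.0

    def test_monotone_transform_null(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=30)
        labels = (s + rng.normal(0, 1, 30) > 0).astype(int)
        labels[0], labels[1] = 0, 1
        auc_a, auc_b, z, p = delong_test(s, 2 * s + 5, labels)
        assert auc_a == pytest.approx(auc_b)
        assert p == pytest.approx(1.0)

    def test_distinguishes_informative_from_noise(self):
        rng = np.random.default_rng(8)
        n = 200
        labels = rng.integers(0, 2, n)
        signal = labels + rng.normal(0, 0.5, n)
        noise = rng.normal(0, 1, n)
        auc_a, auc_b, z, p = delong_test(signal, noise, labels)
        assert auc_a > 0.85 and p < 0.001


class TestIcc:
    def test_identical_raters_give_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert icc_oneway(x) == pytest.approx(1.0)

    def test_hand_anova_oracle_5x2(self):
        x = np.array([[1.0, 2.0], [3.0, 2.5], [5.0, 6.0],
                      [7.0, 6.5], [9.0, 9.5]])
        n, k = x.shape
        grand = x.mean()
        msb = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msw = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (k - 1))
        expected = (msb - msw) / (msb + (k - 1) * msw)
        assert icc_oneway(x) == pytest.approx(expected, abs=1e-12)

    def test_reshuffled_rater_near_zero_in_expectation(self):
        rng = np.random.default_rng(9)
        vals = []
        base = rng.normal(0, 1, 30)
        for _ in range(200):
            x = np.column_stack([base, rng.permutation(base)])
            vals.append(icc_oneway(x))
        assert abs(np.mean(vals)) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_oneway(np.ones((4, 2)))


class TestLogisticCombination:
    def test_coefficients_match_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(10)
        x = rng.normal(size=(200, 3))
        eta = 0.5 + x @ np.array([1.0, -0.7, 0.3])
        y = (rng.uniform(size=200) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = logistic_combination(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert np.allclose(fit.coefficients, ref.params, atol=1e-6)
        assert fit.converged

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(11)
        beta = np.array([0.2, 1.0, -0.5])
        x = rng.normal(size=(500, 2))
        eta = beta[0] + x @ beta[1:]
        y = (rng.uniform(size=500) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = logistic_combination(x, y)
        # asymptotic SE ~ 0.1-0.15 at n=500 for unit-scale features
        assert np.all(np.abs(fit.coefficients - beta) < 0.45)

    def test_single_feature_preserves_ranking_and_auc(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=60)
        y = (x + rng.normal(0, 1, 60) > 0).astype(int)
        fit = logistic_combination(x, y)
        assert roc_auc(fit.probabilities, y).auc == pytest.approx(
            roc_auc(x, y).auc)

    def test_independent_labels_auc_near_half(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(400, 2))
        y = rng.integers(0, 2, 400)
        fit = logistic_combination(x, y)
        assert abs(roc_auc(fit.probabilities, y).auc - 0.5) < 0.08

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(14)
        x = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = rng.integers(0, 2, 50)
        with pytest.warns(UserWarning, match="constant"):
            fit = logistic_combination(x, y)
        assert fit.kept_columns == [1]

    def test_perfect_separation_flagged_probabilities_returned(self):
        x = np.arange(20.0)
        y = (x >= 10).astype(int)
        with pytest.warns(UserWarning, match="separation"):
            fit = logistic_combination(x, y)
        assert fit.separated
        assert np.all(np.isfinite(fit.probabilities))
        assert roc_auc(fit.probabilities, y).auc == 1.0
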