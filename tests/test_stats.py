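import numpy as np
import pytest
from scipy import stats as sps

from plaquekit.stats import (
    anova_tukey,
    bonferroni_per_bin,
    grubbs_critical,
    grubbs_outlier,
    pearson_correlation,
    significance_stars,
    summarise,
    unpaired_t_test,
)


class TestTTest:
    def test_identical_samples(self):
        res = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.df == 4.0

    def test_textbook_formula_oracle(self):
        a = [5.1, 4.9, 5.0, 5.2]
        b = [6.0, 6.1, 5.9, 6.2]
        res = unpaired_t_test(a, b)
        # independent recomputation from the pooled-variance formula
        na, nb = 4, 4
        va = sum((x - np.mean(a)) ** 2 for x in a) / (na - 1)
        vb = sum((x - np.mean(b)) ** 2 for x in b) / (nb - 1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = 2 * sps.t.sf(abs(t), na + nb - 2)
        assert res.statistic == pytest.approx(t, abs=1e-8)
        assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(3, 20))
            b = rng.normal(0.5, 2, rng.integers(3, 20))
            res = unpaired_t_test(a, b)
            ref = sps.ttest_ind(a, b, equal_var=True)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_agrees_with_permutation_approximation(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 8)
        res = unpaired_t_test(a, b)
        pooled = np.concatenate([a, b])
        n_perm = 20000
        t_obs = abs(res.statistic)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            count += abs(sps.ttest_ind(perm[:8], perm[8:]).statistic) >= t_obs
        p_perm = count / n_perm
        mc_se = np.sqrt(p_perm * (1 - p_perm) / n_perm) + 1e-4
        assert abs(res.p_value - p_perm) < 5 * mc_se + 0.01

    def test_sign_flips_under_group_swap(self, rng):
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 6)
        r1, r2 = unpaired_t_test(a, b), unpaired_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_zero_variance_conventions(self):
        res = unpaired_t_test([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0
        with pytest.raises(ValueError, match="zero pooled variance"):
            unpaired_t_test([2.0, 2.0], [3.0, 3.0])

    def test_welch_option(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0, 5, 12)
        res = unpaired_t_test(a, b, welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_type_one_error_nominal(self, rng):
        n_rej = sum(
            unpaired_t_test(rng.normal(0, 1, 8), rng.normal(0, 1, 8)).p_value < 0.05
            for _ in range(400)
        )
        assert 0.02 < n_rej / 400 < 0.08


class TestBonferroni:
    def test_single_bin_unchanged(self):
        assert bonferroni_per_bin([0.03]).tolist() == [0.03]

    def test_closed_form_and_cap(self):
        out = bonferroni_per_bin([0.01, 0.5, 0.001, 0.2, 0.04])
        assert out[0] == pytest.approx(0.05)
        assert out[1] == 1.0

    def test_never_decreases_never_exceeds_one(self, rng):
        p = rng.uniform(0, 1, 50)
        out = bonferroni_per_bin(p)
        assert np.all(out >= p) and np.all(out <= 1.0)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_correlation(x, x).statistic == pytest.approx(1.0)
        assert pearson_correlation(x, -2 * x + 3).statistic == pytest.approx(-1.0)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(0, 1, 20)
            y = 0.5 * x + rng.normal(0, 1, 20)
            res = pearson_correlation(x, y)
            r_ref, p_ref = sps.pearsonr(x, y)
            assert res.statistic == pytest.approx(r_ref, abs=1e-10)
            assert res.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_symmetric_in_x_y(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        assert pearson_correlation(x, y).statistic == pytest.approx(
            pearson_correlation(y, x).statistic
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAnovaTukey:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = anova_tukey({"a": g, "b": g, "c": g})
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_scipy_oracles(self, rng):
        groups = {
            "a": rng.normal(0, 1, 8),
            "b": rng.normal(0.5, 1, 10),
            "c": rng.normal(1.0, 1, 7),
        }
        res = anova_tukey(groups)
        f_ref, p_ref = sps.f_oneway(*groups.values())
        assert res.statistic == pytest.approx(f_ref, abs=1e-6)
        assert res.p_value == pytest.approx(p_ref, abs=1e-6)
        ref = sps.tukey_hsd(*groups.values())
        pairs = {("a", "b"): (0, 1), ("a", "c"): (0, 2), ("b", "c"): (1, 2)}
        for pw in res.pairwise:
            i, j = pairs[(pw.group_a, pw.group_b)]
            assert pw.p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_type_one_error_nominal(self, rng):
        n_rej = 0
        for _ in range(400):
            res = anova_tukey([rng.normal(0, 1, 6) for _ in range(3)])
            n_rej += res.p_value < 0.05
        assert 0.02 < n_rej / 400 < 0.08

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 3 groups"):
            anova_tukey({"a": [1.0, 2.0], "b": [3.0, 4.0]})


class TestGrubbs:
    def test_single_gross_outlier_removed(self):
        kept, removed = grubbs_outlier([10.0, 11.0, 9.0, 10.0, 50.0])
        assert removed == [4]
        assert sorted(kept.tolist()) == [9.0, 10.0, 10.0, 11.0]

    def test_all_equal_none_removed(self):
        kept, removed = grubbs_outlier([5.0, 5.0, 5.0, 5.0])
        assert removed == []

    def test_critical_value_formula(self):
        # independent recomputation of the two-sided critical value
        for n, alpha in ((5, 0.05), (10, 0.05), (20, 0.01)):
            t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
            expected = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
            assert grubbs_critical(n, alpha) == pytest.approx(expected, abs=1e-12)

    def test_decision_uses_critical_value(self, rng):
        # the extreme deviate is removed iff G exceeds the critical value
        for _ in range(50):
            v = rng.normal(0, 1, 10)
            g = np.max(np.abs(v - v.mean())) / v.std(ddof=1)
            _, removed = grubbs_outlier(v)
            assert (len(removed) > 0) == (g > grubbs_critical(10, 0.05))

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            grubbs_outlier([1.0, 2.0])


class TestSummaries:
    def test_sem_definition(self):
        s = summarise([1.0, 2.0, 3.0, 4.0])
        assert s.sem == pytest.approx(np.std([1, 2, 3, 4], ddof=1) / 2.0)

    def test_star_convention(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.001) == "***"
        assert significance_stars(0.01) == "**"
        assert significance_stars(0.05) == "*"
        assert significance_stars(0.051) == "ns"
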