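import itertools

import numpy as np
import pytest
from scipy import stats as sps

from mibcigame import (DataError, ParameterError, RepeatedMeasuresAnova,
                       mann_whitney_u, mauchly, pearson, rm_anova,
                       rm_anova_long, shapiro_wilk, sphericity_epsilons,
                       t_test_ind)


class TestShapiroWilk:
    def test_normal_quantiles_near_one(self):
        x = sps.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        w, p = shapiro_wilk(x)
        assert w > 0.99

    def test_bimodal_rejected(self):
        x = np.concatenate([np.zeros(15), np.ones(15)])
        x += np.linspace(0, 1e-3, 30)  # break exact ties
        _, p = shapiro_wilk(x)
        assert p < 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(DataError):
            shapiro_wilk(np.ones(10))

    def test_sample_size_limits(self):
        with pytest.raises(ParameterError):
            shapiro_wilk([1.0, 2.0])


class TestMannWhitney:
    def test_fully_separated_small_sample_exact(self):
        """{1,2} vs {3,4}: U = 0 and exact two-sided p = 1/3, checked
        against complete enumeration of the 6 label arrangements."""
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        pool = [1, 2, 3, 4]
        u_obs = []
        for xs in itertools.combinations(range(4), 2):
            x = [pool[i] for i in xs]
            y = [pool[i] for i in range(4) if i not in xs]
            u_xy = sum(xi > yj for xi in x for yj in y)
            u_obs.append(min(u_xy, 4 - u_xy))
        p_exact = np.mean([v <= 0 for v in u_obs])
        assert p == pytest.approx(p_exact)
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_central_u(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(x, x)
        assert u == len(x) ** 2 / 2
        assert p > 0.98

    def test_matches_reference_for_shift_alternative(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 12)
        y = rng.normal(1, 1, 15)
        u, p = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="exact")
        assert (u, p) == pytest.approx((ref.statistic, ref.pvalue),
                                       abs=1e-10)

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            mann_whitney_u([], [1.0])


class TestTTest:
    def test_equal_samples_give_zero_t(self):
        t, p = t_test_ind([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_pooled_variance_closed_form(self):
        x = np.array([4.0, 5.0, 6.0, 7.0])
        y = np.array([1.0, 2.0, 3.0])
        t, p = t_test_ind(x, y)
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)
               ) / (len(x) + len(y) - 2)
        t_hand = (x.mean() - y.mean()) / np.sqrt(
            sp2 * (1 / len(x) + 1 / len(y)))
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert p == pytest.approx(
            2 * sps.t.sf(abs(t_hand), len(x) + len(y) - 2), abs=1e-12)

    def test_single_observation_groups_rejected(self):
        with pytest.raises(DataError):
            t_test_ind([1.0], [2.0])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        rho, _ = pearson(x, 2 * x + 1)
        assert rho == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        rho, _ = pearson(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_null_p_values_uniform(self):
        """Independent x, y at n = 14: p-values are Uniform(0, 1)."""
        rng = np.random.default_rng(123)
        ps = [pearson(rng.normal(size=14), rng.normal(size=14))[1]
              for _ in range(1000)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestMauchly:
    def test_two_conditions_trivially_spherical(self):
        data = np.random.default_rng(0).normal(size=(10, 2))
        chi2, df, p = mauchly(data)
        assert (df, p) == (0.0, 1.0)

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        data = rng.normal(size=(12, 4)) * [1.0, 1.5, 2.0, 0.7]
        chi2, df, p = mauchly(data)
        long = pd.DataFrame({
            "s": np.repeat(np.arange(12), 4),
            "c": list(range(4)) * 12,
            "v": data.ravel(),
        })
        ref = pg.sphericity(long, dv="v", within="c", subject="s")
        assert chi2 == pytest.approx(ref.chi2, abs=1e-6)
        assert df == ref.dof
        assert p == pytest.approx(ref.pval, abs=1e-6)

    def test_rejection_rate_near_nominal_under_sphericity(self):
        """Spherical (iid) null: Mauchly rejects at ~alpha."""
        rng = np.random.default_rng(77)
        rejections = sum(
            mauchly(rng.normal(size=(20, 3)))[2] < 0.05 for _ in range(500))
        assert 0.02 <= rejections / 500 <= 0.09

    def test_requires_enough_subjects(self):
        with pytest.raises(ParameterError):
            mauchly(np.zeros((2, 4)))


def brute_force_ss(data):
    """Textbook sums of squares via explicit loops."""
    n, k = data.shape
    grand = data.sum() / (n * k)
    ss_subj = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_cond = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((data[i, j] - grand) ** 2
                 for i in range(n) for j in range(k))
    return ss_cond, ss_tot - ss_subj - ss_cond


class TestRmAnova:
    fixture = np.array([
        [45.0, 50.0, 55.0],
        [42.0, 42.0, 45.0],
        [36.0, 41.0, 43.0],
        [39.0, 35.0, 40.0],
        [51.0, 55.0, 59.0],
        [44.0, 49.0, 56.0],
    ])

    def test_matches_hand_computed_sums_of_squares(self):
        res = rm_anova(self.fixture)
        ss_cond, ss_err = brute_force_ss(self.fixture)
        assert res.ss_condition == pytest.approx(ss_cond, abs=1e-8)
        assert res.ss_error == pytest.approx(ss_err, abs=1e-8)
        assert res.F == pytest.approx(
            (ss_cond / 2) / (ss_err / 10), abs=1e-8)
        assert res.p == pytest.approx(sps.f.sf(res.F, 2, 10), abs=1e-12)

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        n, k = self.fixture.shape
        long = pd.DataFrame({
            "s": np.repeat(np.arange(n), k),
            "c": list(range(k)) * n,
            "v": self.fixture.ravel(),
        })
        ref = pg.rm_anova(data=long, dv="v", within="c", subject="s",
                          correction=True, detailed=True)
        res = rm_anova(self.fixture)
        assert res.ss_condition == pytest.approx(ref["SS"][0], abs=1e-8)
        assert res.ss_error == pytest.approx(ref["SS"][1], abs=1e-8)
        assert res.F == pytest.approx(ref["F"][0], abs=1e-8)
        assert res.p == pytest.approx(ref["p_unc"][0], abs=1e-10)
        assert res.p_gg == pytest.approx(ref["p_GG_corr"][0], abs=1e-8)
        eps_ref = pg.epsilon(long, dv="v", within="c", subject="s",
                             correction="gg")
        assert res.epsilon_gg == pytest.approx(eps_ref, abs=1e-8)

    def test_two_conditions_reproduce_paired_t(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(14, 2)) + [0.0, 0.4]
        res = rm_anova(data)
        t, p = sps.ttest_rel(data[:, 1], data[:, 0])
        assert res.F == pytest.approx(t ** 2, abs=1e-8)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_constant_within_subject_rows(self):
        data = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = rm_anova(data)
        assert res.ss_condition == pytest.approx(0.0)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_epsilon_ordering_invariant(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            data = rng.normal(size=(10, 4)) * rng.uniform(0.5, 3.0, 4)
            res = rm_anova(data)
            k = 4
            assert 1.0 / (k - 1) <= res.epsilon_gg + 1e-12
            assert res.epsilon_gg <= res.epsilon_hf + 1e-12
            assert res.epsilon_hf <= 1.0
            # shrinking both df raises p only well above F = 1; for
            # F < 1 the ordering genuinely reverses
            if res.F >= 2.0:
                assert res.p_lb >= res.p_gg - 1e-12
                assert res.p_gg >= res.p - 1e-12

    def test_location_invariance(self):
        res1 = rm_anova(self.fixture)
        res2 = rm_anova(self.fixture + 1234.5)
        assert res2.F == pytest.approx(res1.F, rel=1e-9)
        assert res2.epsilon_gg == pytest.approx(res1.epsilon_gg, rel=1e-9)

    def test_listwise_deletion_of_incomplete_subjects(self):
        data = np.vstack([self.fixture, [np.nan, 50.0, 51.0]])
        res = rm_anova(data)
        assert res.n_dropped == 1
        assert res.n_subjects == 6
        assert res.F == pytest.approx(rm_anova(self.fixture).F)

    def test_too_small_designs_rejected(self):
        with pytest.raises(ParameterError):
            rm_anova(self.fixture[:, :1])
        with pytest.raises(ParameterError):
            rm_anova(self.fixture[:1])

    def test_long_format_and_model_object_agree(self):
        import pandas as pd

        n, k = self.fixture.shape
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "condition": list(range(k)) * n,
            "value": self.fixture.ravel(),
        })
        res_long = rm_anova_long(long, dv="value", within="condition",
                                 subject="subject")
        res_model = RepeatedMeasuresAnova(self.fixture).fit()
        assert res_long.F == pytest.approx(res_model.F)
        table = res_model.summary()
        assert list(table.columns) == ["SumSq", "df", "MeanSq", "F",
                                       "p-Value", "p-ValueGG", "p-ValueHF",
                                       "p-ValueLB"]


def test_hf_epsilon_classical_formula():
    rng = np.random.default_rng(2)
    data = rng.normal(size=(12, 3)) * [1.0, 2.0, 4.0]
    eps = sphericity_epsilons(data)
    n, k = data.shape
    hf_hand = (n * (k - 1) * eps["gg"] - 2) / (
        (k - 1) * (n - 1 - (k - 1) * eps["gg"]))
    assert eps["hf"] == pytest.approx(min(1.0, hf_hand), abs=1e-12)
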