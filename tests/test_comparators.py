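import itertools

import numpy as np
import pytest
from scipy import stats

from pedigrisk import (
    CRSample,
    binomial_concordance_test,
    icc_kin,
    mean_time_comparison,
    pearson_kin,
    permutation_test,
    yules_q,
)
from pedigrisk.concordance import PairedCRSample


def make_pairs(x, y, status1=None, status2=None):
    n = len(x)
    return PairedCRSample(
        x, status1 if status1 is not None else np.ones(n, int),
        y, status2 if status2 is not None else np.ones(n, int),
        cluster=np.arange(n),
    )


class TestMeanTimeComparison:
    def test_identical_groups_t_zero(self):
        a = CRSample([10.0, 12.0, 14.0], [1, 1, 1])
        res = mean_time_comparison(a, a)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        a = CRSample([10.0, 12.0, 14.0], [1, 1, 1])
        b = CRSample([20.0, 22.0, 24.0], [1, 1, 1])
        res = mean_time_comparison(a, b)
        t, p = stats.ttest_ind([10, 12, 14], [20, 22, 24], equal_var=True)
        assert res.statistic == pytest.approx(t)
        assert res.pvalue == pytest.approx(p)
        assert res.estimate == pytest.approx(-10.0)

    def test_censored_records_excluded_from_numerator(self):
        a = CRSample([10.0, 12.0, 99.0], [1, 1, 0])
        b = CRSample([20.0, 22.0], [1, 1])
        res = mean_time_comparison(a, b)
        assert res.n_used == 4 and res.n_total == 5

    def test_too_few_complete_cases_errors(self):
        a = CRSample([10.0, 12.0], [1, 0])
        with pytest.raises(ValueError, match="complete cases"):
            mean_time_comparison(a, a)

    def test_complete_case_bias_under_censoring_of_long_lifetimes(self):
        # administrative censoring removes long lifetimes, so the
        # complete-case mean underestimates the true mean
        rng = np.random.default_rng(0)
        t = rng.lognormal(np.log(20), 0.5, 4000)
        status = np.where(t >= 30.0, 0, 1)
        obs = np.minimum(t, 30.0)
        sample = CRSample(obs, status)
        complete_mean = sample.time[sample.status == 1].mean()
        assert complete_mean < t.mean()


class TestPearsonKin:
    def test_identity_line_r_one(self):
        t = np.array([5.0, 10.0, 15.0, 20.0])
        res = pearson_kin(make_pairs(t, t), seed=0)
        assert res.estimate == pytest.approx(1.0)

    def test_five_pair_fixture_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.5, 2.1, 2.9, 4.4, 4.9])
        res = pearson_kin(make_pairs(x, y), seed=0)
        # reproduce the seeded member-order flip, then the closed form
        flip = np.random.default_rng(0).uniform(size=5) < 0.5
        xf = np.where(flip, y, x)
        yf = np.where(flip, x, y)
        assert res.estimate == pytest.approx(
            stats.pearsonr(xf, yf).statistic, abs=1e-12)

    def test_complete_case_only(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_kin(make_pairs(x, x, status2=[1, 1, 1, 0]), seed=0)
        assert res.n_used == 3 and res.n_total == 4

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError, match="< 3"):
            pearson_kin(make_pairs([1.0, 2.0], [1.0, 2.0]))


class TestIccKin:
    def test_identical_members_icc_one(self):
        t = np.array([5.0, 10.0, 15.0, 20.0])
        res = icc_kin(make_pairs(t, t))
        assert res.estimate == pytest.approx(1.0)

    def test_matches_anova_oracle(self, rng):
        x = rng.normal(20, 5, 30)
        y = x + rng.normal(0, 2, 30)
        res = icc_kin(make_pairs(x, y))
        import pingouin as pg
        import pandas as pd

        long = pd.DataFrame({
            "targets": np.repeat(np.arange(30), 2),
            "raters": np.tile([0, 1], 30),
            "score": np.column_stack([x, y]).ravel(),
        })
        icc1 = pg.intraclass_corr(long, targets="targets", raters="raters",
                                  ratings="score").set_index("Type")
        assert res.estimate == pytest.approx(icc1.loc["ICC(1,1)", "ICC"],
                                             abs=1e-9)

    def test_order_symmetric(self, rng):
        x = rng.normal(20, 5, 25)
        y = x + rng.normal(0, 3, 25)
        assert icc_kin(make_pairs(x, y)).estimate == pytest.approx(
            icc_kin(make_pairs(y, x)).estimate)


class TestYulesQ:
    def test_fully_concordant_is_one(self):
        res = yules_q([[30, 0], [0, 10]])
        assert res.estimate == 1.0

    def test_closed_form_example(self):
        res = yules_q([[30, 10], [10, 30]])
        assert res.estimate == pytest.approx(0.8)  # (900-100)/(900+100)

    def test_undefined_when_ad_and_bc_zero(self):
        with pytest.raises(ValueError, match="undefined"):
            yules_q([[0, 5], [0, 5]])


class TestPermutationTest:
    def test_synchronised_pairs_minimal_p(self):
        base = np.array([5.0, 15.0, 30.0, 50.0, 70.0])
        res = permutation_test(make_pairs(base, base), n_perm=500, seed=0)
        assert res.observed == 0.0
        assert res.null_mean > 0
        assert res.pvalue == pytest.approx(1 / 501)
        assert res.statistic > 0

    def test_exhaustive_three_pair_oracle(self):
        x = np.array([1.0, 5.0, 9.0])
        y = np.array([2.0, 6.0, 11.0])
        pool = np.concatenate([x, y])
        # enumerate all 15 pairings of 6 elements into 3 unordered pairs
        vals = []
        first = pool[0]
        rest = list(pool[1:])
        for mate_idx in range(5):
            mate = rest[mate_idx]
            o = [v for i, v in enumerate(rest) if i != mate_idx]
            splits = [((o[0], o[1]), (o[2], o[3])),
                      ((o[0], o[2]), (o[1], o[3])),
                      ((o[0], o[3]), (o[1], o[2]))]
            for p2, p3 in splits:
                diffs = [abs(first - mate), abs(p2[0] - p2[1]),
                         abs(p3[0] - p3[1])]
                vals.append(np.mean(diffs))
        assert len(vals) == 15
        mu_exact, sd_exact = np.mean(vals), np.std(vals, ddof=0)
        res = permutation_test(make_pairs(x, y), n_perm=20000, seed=1)
        assert res.null_mean == pytest.approx(mu_exact, rel=0.03)
        assert res.null_sd == pytest.approx(sd_exact, rel=0.10)

    def test_determinism_and_nperm_floor(self):
        x = np.array([1.0, 5.0, 9.0, 12.0])
        y = x + 1
        r1 = permutation_test(make_pairs(x, y), n_perm=200, seed=3)
        r2 = permutation_test(make_pairs(x, y), n_perm=200, seed=3)
        assert r1.pvalue == r2.pvalue and r1.null_mean == r2.null_mean
        with pytest.raises(ValueError, match="100"):
            permutation_test(make_pairs(x, y), n_perm=50, seed=0)


class TestBinomialConcordance:
    def test_half_at_null_p_one(self):
        res = binomial_concordance_test(5, 10, 0.5)
        assert res.pvalue == pytest.approx(1.0)

    def test_all_concordant_closed_form(self):
        res = binomial_concordance_test(10, 10, 0.5)
        assert res.pvalue == pytest.approx(2 * 0.5**10)

    def test_symmetry_zero_vs_all(self):
        assert binomial_concordance_test(0, 8, 0.5).pvalue == pytest.approx(
            binomial_concordance_test(8, 8, 0.5).pvalue)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            binomial_concordance_test(0, 0, 0.5)
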