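import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from pedigrisk import (
    CompetingRisksRegression,
    CRSample,
    aalen_johansen_cif,
    extract_kin_pairs,
    pair_sample,
    simulate_pedigrees,
    SimConfig,
    to_cr_sample,
)
from pedigrisk.crr import ConvergenceError, threshold_scan
from pedigrisk.simulate import simulate_crr_sample

CAUSE_MAP = {"division": 1, "death": 2, "lost": 0, "end_of_observation": 0}


class TestOneSampleReduction:
    @pytest.mark.parametrize("link", ["additive", "proportional"])
    def test_baseline_only_equals_aalen_johansen(self, link, rng):
        for _ in range(10):
            s = simulate_crr_sample(n=int(rng.integers(50, 300)), gamma=0.5,
                                    seed=int(rng.integers(2**31)))
            fit = CompetingRisksRegression(s, "CIF ~ 1", cause=1,
                                           link=link).fit()
            pred = fit.predict_cif({}, n_resample=50, seed=0)
            aj = aalen_johansen_cif(s, 1)
            assert np.max(np.abs(pred.values - aj.at(fit.grid))) <= 1e-6


class TestParameterRecovery:
    def test_proportional_gamma_within_three_se(self):
        s = simulate_crr_sample(n=2000, gamma=0.7, seed=77)
        fit = CompetingRisksRegression(s, "CIF ~ 1 + const(z)", cause=1,
                                       max_grid=60).fit()
        g, se = fit.params_const["const(z)"], fit.bse["const(z)"]
        assert abs(g - 0.7) < 3 * se
        assert fit.pvalues["const(z)"] < 0.01

    def test_additive_slope_within_three_se(self):
        s = simulate_crr_sample(n=2000, link="additive", seed=78)
        fit = CompetingRisksRegression(s, "CIF ~ 1 + const(z)", cause=1,
                                       link="additive", max_grid=60).fit()
        g, se = fit.params_const["const(z)"], fit.bse["const(z)"]
        assert abs(g - 0.004) < 3 * se

    def test_default_link_follows_const_terms(self):
        s = simulate_crr_sample(n=200, seed=1)
        assert CompetingRisksRegression(s, "CIF ~ 1 + const(z)").link == \
            "proportional"
        assert CompetingRisksRegression(s, "CIF ~ 1 + z",
                                        link="additive").link == "additive"


class TestPrediction:
    def test_additive_profile_adds_cumulative_coefficient(self):
        s = simulate_crr_sample(n=800, gamma=0.6, seed=5)
        fit = CompetingRisksRegression(s, "CIF ~ 1 + z", cause=1,
                                       link="additive", max_grid=40).fit()
        base = fit.predict_cif({"z": 0.0}, n_resample=50, seed=0)
        treated = fit.predict_cif({"z": 1.0}, n_resample=50, seed=0)
        j = fit.model.varying_names.index("z")
        manual = np.clip(base.values + fit.paths[:, j], 0, 1)
        assert np.allclose(treated.values, manual, atol=1e-12)

    def test_profile_missing_covariate_errors(self):
        s = simulate_crr_sample(n=200, seed=2)
        fit = CompetingRisksRegression(s, "CIF ~ 1 + z", cause=1).fit()
        with pytest.raises(KeyError, match="missing covariates"):
            fit.predict_cif({})

    def test_zeroed_coefficient_gives_identical_curves(self):
        s = simulate_crr_sample(n=400, gamma=0.7, seed=3)
        fit = CompetingRisksRegression(s, "CIF ~ 1 + const(z)", cause=1,
                                       max_grid=40).fit()
        fit.gamma = np.zeros_like(fit.gamma)  # force a null effect
        a = fit.predict_cif({"z": 0.0}, n_resample=50, seed=0)
        b = fit.predict_cif({"z": 1.0}, n_resample=50, seed=0)
        assert np.array_equal(a.values, b.values)

    def test_proportional_predictions_conserve_mass(self):
        s = simulate_crr_sample(n=800, gamma=0.7, seed=9)
        total = np.zeros(1)
        curves = []
        for cause in (1, 2):
            fit = CompetingRisksRegression(s, "CIF ~ 1 + const(z)",
                                           cause=cause, max_grid=40).fit()
            curves.append(fit.predict_cif({"z": 1.0}, n_resample=50, seed=0))
        t_end = min(c.times[-1] for c in curves)
        total = sum(c.at(t_end) for c in curves)
        assert total <= 1.0 + 1e-6


class TestTimeInvariance:
    def test_deterministic_for_fixed_seed(self):
        s = simulate_crr_sample(n=400, gamma=0.5, seed=21)
        fit = CompetingRisksRegression(s, "CIF ~ 1 + z", cause=1,
                                       link="proportional", max_grid=40).fit()
        p1 = fit.test_time_invariance("z", n_resample=200, seed=11).pvalue
        p2 = fit.test_time_invariance("z", n_resample=200, seed=11).pvalue
        assert p1 == p2

    def test_small_resample_count_rejected(self):
        s = simulate_crr_sample(n=200, seed=4)
        fit = CompetingRisksRegression(s, "CIF ~ 1 + z", cause=1).fit()
        with pytest.raises(ValueError, match="50"):
            fit.test_time_invariance("z", n_resample=10)

    def test_type_one_error_calibrated(self):
        # truly constant effect: rejection rate compatible with alpha=0.05
        rej = 0
        n_sim = 200
        for rep in range(n_sim):
            s = simulate_crr_sample(n=300, gamma=0.5, seed=10_000 + rep)
            fit = CompetingRisksRegression(s, "CIF ~ 1 + z", cause=1,
                                           link="proportional",
                                           max_grid=40).fit()
            res = fit.test_time_invariance("z", n_resample=200, seed=rep)
            rej += res.pvalue < 0.05
        rate = rej / n_sim
        # within 3 binomial standard errors of the nominal level
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_power_against_sign_reversing_effect(self):
        def sim(n, seed):
            rng = np.random.default_rng(seed)
            z = (rng.uniform(size=n) < 0.5).astype(float)
            u = rng.uniform(size=n)
            t = np.where(z == 0, st.lognorm(0.4, scale=18).ppf(u),
                         st.lognorm(0.25, scale=8).ppf(u))
            is1 = rng.uniform(size=n) < 0.55
            t2 = st.lognorm(0.5, scale=15).rvs(size=n, random_state=rng)
            tt = np.where(is1, t, t2)
            ss = np.where(is1, 1, 2)
            c = np.minimum(rng.exponential(50, n), 72)
            ss = np.where(tt >= c, 0, ss)
            return CRSample(np.maximum(np.minimum(tt, c), 1e-9), ss,
                            pd.DataFrame({"z": z}))

        rej = 0
        for rep in range(20):
            s = sim(1500, 30_000 + rep)
            fit = CompetingRisksRegression(s, "CIF ~ 1 + z", cause=1,
                                           link="proportional",
                                           max_grid=40).fit()
            rej += fit.test_time_invariance("z", n_resample=200,
                                            seed=rep).pvalue < 0.05
        assert rej / 20 >= 0.8


class TestVarianceStructure:
    def test_cluster_robust_at_least_naive_under_clustering(self):
        forest, _, _ = simulate_pedigrees(SimConfig(
            seed=42, n_founders=150, max_generations=5, frailty_theta=3.0,
            frailty_mode="shared", frailty_level="parent"))
        sample, _ = to_cr_sample(forest, CAUSE_MAP)
        pairs = extract_kin_pairs(forest, "sibling")
        paired = pair_sample(sample, pairs)
        ids = np.concatenate([paired.ids1, paired.ids2])
        cluster = np.concatenate([paired.cluster, paired.cluster])
        keep = ~pd.Index(ids).duplicated()
        idx = {cid: i for i, cid in enumerate(sample.ids)}
        rows = [idx[c] for c in ids[keep]]
        sub = sample.subset(np.isin(np.arange(sample.n), rows))
        cl = pd.Series(dict(zip(ids[keep], cluster[keep])))
        treat = (pd.Series(sub.ids).map(
            lambda c: hash(cl[c]) % 2).to_numpy().astype(float))
        s2 = CRSample(sub.time, sub.status,
                      pd.DataFrame({"treat": treat, "sib": cl[sub.ids].to_numpy()}))
        fit = CompetingRisksRegression(
            s2, "CIF ~ 1 + const(treat) + cluster(sib)", cause=1,
            max_grid=40).fit()
        assert fit.bse["const(treat)"] >= 0.95 * fit.bse_naive["const(treat)"]

    def test_singular_design_names_collinear_terms(self):
        s = simulate_crr_sample(n=200, seed=6)
        s.covariates["z2"] = s.covariates["z"]
        with pytest.raises(np.linalg.LinAlgError, match="z2"):
            CompetingRisksRegression(s, "CIF ~ 1 + z + z2", cause=1)

    def test_nonconvergence_carries_last_iterate(self):
        s = simulate_crr_sample(n=500, gamma=1.5, seed=8)
        model = CompetingRisksRegression(s, "CIF ~ 1 + const(z)", cause=1,
                                         max_grid=30)
        with pytest.raises(ConvergenceError) as exc:
            model.fit(max_iter=1, tol=1e-14)
        assert exc.value.gamma is not None


class TestThresholdScan:
    @staticmethod
    def _sim(n, true_thresh, seed, effect=1.5):
        rng = np.random.default_rng(seed)
        inten = rng.uniform(0, 200, n)
        partner = (rng.uniform(size=n) < 0.5).astype(float)
        g = effect * ((inten > true_thresh) * partner)
        p0 = 0.45
        u = rng.uniform(size=n)
        p1 = 1 - (1 - p0) ** np.exp(g)
        is1 = u < p1
        v = 1 - (1 - u) ** np.exp(-g)
        t = np.where(is1, -12 * np.log1p(-np.clip(v / p0, 0, 1 - 1e-12)),
                     st.lognorm(0.5, scale=15).rvs(size=n, random_state=rng))
        status = np.where(is1, 1, 2)
        c = np.minimum(rng.exponential(60, n), 72)
        status = np.where(t >= c, 0, status)
        return CRSample(np.maximum(np.minimum(t, c), 1e-9), status,
                        pd.DataFrame({"intensity": inten, "partner": partner}))

    def test_recovers_known_threshold_within_one_step(self):
        hits = 0
        n_sim = 30
        for rep in range(n_sim):
            s = self._sim(2000, 100.0, 40_000 + rep)
            res = threshold_scan(s, "intensity", "partner",
                                 grid=np.arange(20, 200, 20.0))
            if (res["threshold"] is not None and not res["unstable"]
                    and abs(res["threshold"] - 100.0) <= 20.0):
                hits += 1
        assert hits / n_sim >= 0.8

    def test_no_effect_flagged_unstable(self):
        s = self._sim(1500, np.inf, 7)
        res = threshold_scan(s, "intensity", "partner",
                             grid=np.arange(20, 200, 20.0))
        assert res["unstable"]

    def test_grid_outside_range_errors(self):
        s = self._sim(200, 100.0, 1)
        with pytest.raises(ValueError, match="range"):
            threshold_scan(s, "intensity", "partner", grid=[500.0])

    def test_full_grid_recovers_full_data_effect(self):
        s = self._sim(1500, 100.0, 2)
        full = CompetingRisksRegression(s, "CIF ~ 1 + const(partner)",
                                        cause=1, max_grid=40).fit()
        res = threshold_scan(s, "intensity", "partner",
                             grid=[float(s.covariates["intensity"].max())])
        # the top candidate excludes only the single maximum-intensity cell
        assert res["scan"]["partner_coef"].iloc[-1] == pytest.approx(
            full.params_const.iloc[0], abs=0.02)


class TestReporting:
    def test_summary_mentions_terms_and_link(self):
        s = simulate_crr_sample(n=300, gamma=0.7, seed=12)
        fit = CompetingRisksRegression(s, "CIF ~ 1 + const(z)", cause=1,
                                       max_grid=30).fit()
        text = fit.summary()
        assert "const(z)" in text and "proportional" in text
        d = fit.to_dict()
        assert d["converged"] and len(d["gamma"]) == 1
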