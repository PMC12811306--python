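"""Scalar statistics against independent oracles; mixed models on
simulated data with known coefficients."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import utitask as ut
from utitask.stats import ModelFit, ModelSpec, standardize_uti


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert ut.pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert ut.pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=30)
            y = 0.4 * x + rng.normal(size=30)
            r, p, n = ut.pearson_r(x, y)
            ref = sps.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            assert n == 30

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ut.pearson_r(np.ones(10), np.arange(10.0))


class TestWelch:
    def test_identical_groups_give_zero_t(self):
        g = np.arange(10.0)
        out = ut.welch_t(g, g)
        assert out["t"] == pytest.approx(0.0, abs=1e-12)

    def test_equal_variance_equal_n_reduces_to_student_df(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=20)
        b = a + 0.5  # identical sample variance, shifted mean
        out = ut.welch_t(a, b)
        assert out["df"] == pytest.approx(38.0, abs=1e-9)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(5, 40))
            b = rng.normal(0.3, 2, size=rng.integers(5, 40))
            out = ut.welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert out["t"] == pytest.approx(ref.statistic, abs=1e-12)
            assert out["p"] == pytest.approx(ref.pvalue, abs=1e-12)
            assert out["df"] == pytest.approx(ref.df, abs=1e-10)


class TestCohensD:
    def test_identical_groups_give_zero_with_symmetric_ci(self):
        g = np.arange(20.0)
        d, lo, hi = ut.cohens_d_ci(g, g)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_unit_shift_recovers_d_of_one(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 10_000)
        b = rng.normal(1, 1, 10_000)
        d, lo, hi = ut.cohens_d_ci(b, a)
        assert d == pytest.approx(1.0, abs=0.05)
        assert lo < d < hi

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 35)
        b = rng.normal(0.4, 1.3, 28)
        d, lo, hi = ut.cohens_d_ci(a, b)
        na, nb = len(a), len(b)
        pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                         / (na + nb - 2))
        d_ref = (a.mean() - b.mean()) / pooled
        se_ref = np.sqrt((na + nb) / (na * nb) + d_ref ** 2 / (2 * (na + nb)))
        assert d == pytest.approx(d_ref, abs=1e-12)
        assert hi - lo == pytest.approx(2 * 1.959963984540054 * se_ref,
                                        abs=1e-9)

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (20, 80, 320):
            a = rng.standard_normal(n)
            b = rng.standard_normal(n) + 0.4
            d, lo, hi = ut.cohens_d_ci(a, b)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


class TestPower:
    def test_fisher_z_closed_form_values(self):
        assert ut.power_n_for_r(0.21, alpha=0.05, power=0.90, tails=2) == 235

    def test_monotone_nonincreasing_in_r(self):
        ns = [ut.power_n_for_r(r) for r in (0.1, 0.2, 0.3, 0.5, 0.9)]
        assert ns == sorted(ns, reverse=True)

    def test_extreme_r_matches_direct_evaluation(self):
        import math
        r = 0.9999
        za = sps.norm.ppf(0.975)
        zp = sps.norm.ppf(0.90)
        expected = math.ceil(((za + zp) / math.atanh(r)) ** 2 + 3)
        assert ut.power_n_for_r(r) == expected

    def test_invalid_queries_rejected(self):
        for bad in (dict(r=0.0), dict(r=1.2), dict(r=0.3, alpha=0.0),
                    dict(r=0.3, power=0.01), dict(r=0.3, tails=3)):
            with pytest.raises(ValueError):
                ut.power_n_for_r(**bad)


def simulate_lmm_data(seed, n_participants=60, n_stimuli=16, beta=None):
    """Data generated directly from the crossed-intercepts linear model
    (independent of the cohort simulator)."""
    rng = np.random.default_rng(seed)
    beta = beta or {"Intercept": 800.0, "food_healthy": 20.0,
                    "cls_not_tasty": 100.0, "uti_z": 30.0,
                    "food_healthy:uti_z": -15.0}
    rows = []
    b_p = rng.normal(0, 40, n_participants)
    b_s = rng.normal(0, 20, n_stimuli)
    uti = rng.normal(0, 1, n_participants)
    for i in range(n_participants):
        for j in range(n_stimuli):
            food = float(j < n_stimuli // 2)
            cls = float(rng.random() < 0.25)
            y = (beta["Intercept"] + beta["food_healthy"] * food
                 + beta["cls_not_tasty"] * cls + beta["uti_z"] * uti[i]
                 + beta["food_healthy:uti_z"] * food * uti[i]
                 + b_p[i] + b_s[j] + rng.normal(0, 60))
            rows.append((f"p{i}", f"s{j}", food, cls, uti[i], y))
    df = pd.DataFrame(rows, columns=["participant_id", "stimulus_id",
                                     "food_healthy", "cls_not_tasty",
                                     "uti_z", "rt_ms"])
    return df, beta


class TestLMM:
    def test_parameter_recovery_within_two_se(self):
        spec = ModelSpec(outcome="rt_ms", covariates=())
        hits, total = 0, 0
        for seed in range(6):
            data, beta = simulate_lmm_data(seed)
            fit = ut.fit_lmm(spec, data)
            assert fit.converged
            for name, true in beta.items():
                est = fit.coef.loc[name]
                hits += abs(est["estimate"] - true) <= 2 * est["se"]
                total += 1
        assert hits / total >= 0.90

    def test_constant_outcome_degenerates_cleanly(self):
        data, _ = simulate_lmm_data(1, n_participants=10, n_stimuli=4)
        data["rt_ms"] = 700.0
        fit = ut.fit_lmm(ModelSpec(outcome="rt_ms", covariates=()), data)
        assert fit.coef.loc["Intercept", "estimate"] == 700.0
        assert all(v == 0 for k, v in fit.variance_components.items()
                   if k != "residual")

    def test_variance_components_positive_when_present(self):
        data, _ = simulate_lmm_data(2)
        fit = ut.fit_lmm(ModelSpec(outcome="rt_ms", covariates=()), data)
        assert fit.variance_components["participant"] > 0
        assert fit.variance_components["stimulus"] > 0


class TestSimpleSlopes:
    @staticmethod
    def hand_built_fit(estimates, cov):
        names = ["Intercept", "food_healthy", "cls_not_tasty", "uti_z",
                 "food_healthy:uti_z", "cls_not_tasty:uti_z",
                 "food_healthy:cls_not_tasty:uti_z"]
        coef = pd.DataFrame({"estimate": estimates,
                             "se": np.sqrt(np.diag(cov))}, index=names)
        coef["stat"] = coef["estimate"] / coef["se"]
        coef["p"] = np.nan
        return ModelFit(coef, pd.DataFrame(cov, index=names, columns=names),
                        {}, 100, True)

    def test_zero_interactions_give_zero_contrasts(self):
        est = [800.0, 10.0, 50.0, 30.0, 0.0, 0.0, 0.0]
        fit = self.hand_built_fit(est, np.eye(7))
        for res in ut.simple_slopes(fit):
            assert res.estimate == 0.0

    def test_matches_algebraic_linear_combination(self):
        rng = np.random.default_rng(7)
        est = rng.normal(0, 10, 7)
        a = rng.normal(size=(7, 7))
        cov = a @ a.T / 10
        fit = self.hand_built_fit(est, cov)
        res = {r.label.split("| ")[1]: r for r in ut.simple_slopes(fit)}
        # tasty (cls=0): difference is just the two-way term
        assert res["tasty"].estimate == pytest.approx(est[4], abs=1e-12)
        assert res["tasty"].se == pytest.approx(np.sqrt(cov[4, 4]),
                                                abs=1e-12)
        # not_tasty (cls=1): two-way + three-way, with covariance
        assert res["not_tasty"].estimate == pytest.approx(est[4] + est[6],
                                                          abs=1e-12)
        se_ref = np.sqrt(cov[4, 4] + cov[6, 6] + 2 * cov[4, 6])
        assert res["not_tasty"].se == pytest.approx(se_ref, abs=1e-12)
        assert res["tasty"].z == pytest.approx(
            res["tasty"].estimate / res["tasty"].se)

    def test_tasty_only_conflict_shows_up_in_tasty_cell(self):
        """The generator routes trait conflict through healthy-tasty
        trials; the slope contrast should be significant there and
        (mostly) not within not-tasty responses."""
        sig_tasty, sig_not = 0, 0
        for seed in range(5):
            p, t, s, _ = ut.simulate_cohort(
                ut.SimulationConfig(n_participants=120, seed=500 + seed))
            m = ut.compute_trial_metrics(s, t, include_sample_entropy=False)
            mf, _ = ut.exclude_outliers(m)
            data = ut.prepare_trial_data(mf, t, p, outcome="rt_ms")
            fit = ut.fit_lmm(ModelSpec(outcome="rt_ms"), data)
            res = {r.label.split("| ")[1]: r for r in ut.simple_slopes(fit)}
            sig_tasty += res["tasty"].p < 0.05
            sig_not += res["not_tasty"].p < 0.05
        assert sig_tasty >= 4
        assert sig_not <= sig_tasty

    def test_missing_interaction_is_an_error(self):
        coef = pd.DataFrame({"estimate": [1.0], "se": [1.0],
                             "stat": [1.0], "p": [0.3]}, index=["uti_z"])
        fit = ModelFit(coef, pd.DataFrame([[1.0]], index=["uti_z"],
                                          columns=["uti_z"]), {}, 10, True)
        with pytest.raises(ValueError):
            ut.simple_slopes(fit)


class TestGLMMChoice:
    def test_interaction_sign_recovered_across_seeds(self):
        correct = 0
        for seed in range(5):
            p, t, s, _ = ut.simulate_condition_experiment(
                ut.SimulationConfig(seed=700 + seed), n_per_arm=60)
            m = ut.compute_trial_metrics(s, t, include_sample_entropy=False)
            mf, _ = ut.exclude_outliers(m)
            data = ut.prepare_trial_data(mf, t, p, outcome="rt_ms")
            fit = ut.fit_glmm_choice(data)
            term = "condition_hedonic:food_healthy"
            correct += fit.coef.loc[term, "estimate"] < 0
        assert correct >= 4

    def test_constant_outcome_flagged(self):
        data = pd.DataFrame({
            "tasty": np.ones(40),
            "condition_hedonic": np.r_[np.zeros(20), np.ones(20)],
            "food_healthy": np.tile([0.0, 1.0], 20),
            "participant_id": np.repeat([f"p{i}" for i in range(8)], 5),
            "stimulus_id": np.tile([f"s{i}" for i in range(5)], 8)})
        with pytest.raises(ut.ModelError):
            ut.fit_glmm_choice(data)


class TestIncrementalValidity:
    @staticmethod
    def toy_indices(seed, effect=0.0, n=150):
        rng = np.random.default_rng(seed)
        uti = rng.normal(0, 1, n)
        dmad = 0.5 * uti + rng.normal(0, 1, n)
        dqs = 10 - uti + effect * dmad + rng.normal(0, 2, n)
        return pd.DataFrame({"uti_explicit": 4 + uti, "delta_mad_px": dmad,
                             "dqs": dqs})

    def test_duplicate_predictor_is_singular(self):
        idx = self.toy_indices(0)
        idx["dup"] = idx["uti_explicit"]
        out = ut.incremental_validity(idx, added="dup", covariates=())
        assert out["singular"]

    def test_null_added_variable_rarely_significant(self):
        hits = sum(
            ut.incremental_validity(self.toy_indices(seed), "delta_mad_px",
                                    covariates=())["p"] < 0.05
            for seed in range(40))
        assert hits <= 6  # ~5% expected under the null

    def test_true_incremental_signal_detected(self):
        hits = sum(
            ut.incremental_validity(
                self.toy_indices(seed, effect=-0.8), "delta_mad_px",
                covariates=())["p"] < 0.05
            for seed in range(10))
        assert hits >= 9

    def test_f_change_matches_statsmodels_anova(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        idx = self.toy_indices(3, effect=-0.5)
        out = ut.incremental_validity(idx, "delta_mad_px", covariates=())
        reduced = smf.ols("dqs ~ uti_explicit", idx).fit()
        full = smf.ols("dqs ~ uti_explicit + delta_mad_px", idx).fit()
        table = anova_lm(reduced, full)
        assert out["f_change"] == pytest.approx(table["F"].iloc[1],
                                                abs=1e-10)
        assert out["p"] == pytest.approx(table["Pr(>F)"].iloc[1], abs=1e-12)


def test_standardize_uti_is_unit_scale_over_participants():
    df = pd.DataFrame({
        "participant_id": np.repeat(["a", "b", "c", "d"], 3),
        "uti_explicit": np.repeat([1.0, 3.0, 5.0, 7.0], 3)})
    z = standardize_uti(df)
    per_p = df.assign(z=z).drop_duplicates("participant_id")["z"]
    assert per_p.mean() == pytest.approx(0.0, abs=1e-12)
    assert per_p.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
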