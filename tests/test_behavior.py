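"""Behavioural metrics and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adaptpe import (
    generate_experiment,
    group_tests,
    model_r2,
    pearson_chi2,
    performance_error,
    performance_regression,
    residualize,
    running_mean_agent,
    scaling_contingency,
)


def _trials(predictions, ev=35.0, sd=5.0):
    n = len(predictions)
    return pd.DataFrame({
        "agent_id": "a", "session": 1, "block": 1,
        "trial": np.arange(1, n + 1), "dist_id": "d", "ev": ev, "sd": sd,
        "cue_level": "small", "is_control": False, "reward": 50.0,
        "prediction": predictions, "missed": False, "pe": 0.0, "payoff": 0.0,
    })


class TestPerformanceError:
    def test_mean_absolute_distance_to_ev(self):
        assert performance_error(_trials([30.0, 40.0]),
                                 by_sd=False) == pytest.approx(5.0)

    def test_perfect_predictor_scores_zero(self):
        assert performance_error(_trials([35.0, 35.0]),
                                 by_sd=False) == pytest.approx(0.0)

    def test_all_missed_rejected(self):
        t = _trials([35.0, 35.0]).assign(missed=True)
        with pytest.raises(ValueError):
            performance_error(t)

    def test_running_mean_agent_error_increases_with_sd(self):
        """Even the optimal running-mean strategy incurs error that grows
        with reward variability (the pattern behind the SD conditions)."""
        worse = 0
        n_seeds = 30
        for seed in range(n_seeds):
            t = running_mean_agent(generate_experiment(seed=seed))
            perf = performance_error(t)
            if perf["sd5"] < perf["sd10"] < perf["sd15"]:
                worse += 1
        assert worse / n_seeds > 0.8


class TestScalingContingency:
    def test_reproduces_published_style_counts(self):
        nu = pd.Series([0.0] * 8 + [0.5] * 11 + [0.0] * 2 + [0.7] * 18)
        groups = pd.Series(["sulpiride"] * 19 + ["placebo"] * 20)
        table = scaling_contingency(nu, groups, ("sulpiride", "placebo"))
        assert table.tolist() == [[8, 11], [2, 18]]

    def test_epsilon_one_marks_everyone_nonscaler(self):
        nu = pd.Series([0.2, 0.9, 1.0, 0.0])
        groups = pd.Series(["a", "a", "b", "b"])
        table = scaling_contingency(nu, groups, ("a", "b"), epsilon=1.0)
        assert table[:, 1].sum() == 0

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            scaling_contingency(pd.Series([0.1]), pd.Series(["a"]),
                                ("a", "missing"))


class TestPearsonChi2:
    def test_published_contingency_value(self):
        stat, df, p = pearson_chi2([[8, 11], [2, 18]])
        assert round(stat, 2) == 5.27
        assert df == 1
        assert p == pytest.approx(0.0217, abs=5e-4)

    def test_independent_table_is_zero(self):
        stat, _, _ = pearson_chi2([[5, 5], [5, 5]])
        assert stat == pytest.approx(0.0)

    def test_perfect_association(self):
        stat, _, _ = pearson_chi2([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 5], [0, 5]])


class TestResidualize:
    def test_orthogonal_covariate_leaves_zscored_outcome(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.array([1.0, -1.0, -1.0, 1.0])  # exactly uncorrelated with y
        out = residualize(y, x)
        z = (y - y.mean()) / y.std(ddof=0)
        assert np.allclose(out, z)

    def test_fully_explained_outcome_flagged(self):
        x = np.arange(5, dtype=float)
        with pytest.raises(ValueError):
            residualize(2 * x, x)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            residualize(np.arange(4.0), np.ones(4))

    def test_idempotent_up_to_zscoring(self):
        rng = np.random.default_rng(0)
        y, x = rng.normal(size=30), rng.normal(size=30)
        once = residualize(y, x)
        twice = residualize(once, x)
        assert np.allclose(once, twice, atol=1e-10)

    def test_group_differences_unbiased_after_covariate_removal(self):
        """Adding a covariate effect b*x to simulated outcomes leaves the
        group difference on residuals unbiased."""
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(200):
            groups = np.repeat([0, 1], 20)
            x = rng.normal(size=40)
            y = 0.8 * groups + 2.0 * x + rng.normal(size=40)
            res = residualize(y, x)
            diffs.append(res[groups == 1].mean() - res[groups == 0].mean())
        # standardized true effect 0.8 / sd(y_resid ~ sqrt(0.16+1)) ~ 0.74
        assert np.mean(diffs) == pytest.approx(0.74, abs=0.1)


class TestGroupTests:
    def test_two_groups_match_pairwise_test(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=30)
        groups = np.array(["placebo"] * 15 + ["drug"] * 15)
        out = group_tests(vals, groups, control="placebo")
        assert out["omnibus"]["p"] == pytest.approx(out["posthoc"][0]["p"],
                                                    abs=1e-10)

    def test_type_one_error_calibrated(self):
        """Omnibus false-positive rate sits at the nominal 5% under the
        null of identical group distributions."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_sims = 2000
        groups = np.repeat(["placebo", "a", "b"], 19)
        for _ in range(n_sims):
            vals = rng.normal(size=57)
            _, p = stats.f_oneway(vals[:19], vals[19:38], vals[38:])
            rejections += p < 0.05
        assert abs(rejections / n_sims - 0.05) < 0.02

    def test_power_monotone_in_shift(self):
        rng = np.random.default_rng(4)
        groups = np.repeat(["placebo", "drug"], 19)
        power = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            hits = 0
            for _ in range(150):
                vals = rng.normal(size=38)
                vals[19:] += shift
                out = group_tests(vals, groups, control="placebo")
                hits += out["omnibus"]["p"] < 0.05
            power.append(hits / 150)
        assert all(a <= b + 0.05 for a, b in zip(power, power[1:]))
        assert power[-1] > power[0]

    def test_small_groups_flagged_underpowered(self):
        vals = np.arange(6.0)
        groups = np.array(["placebo"] * 3 + ["drug"] * 3)
        assert group_tests(vals, groups)["underpowered"]

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            group_tests(np.arange(3.0),
                        np.array(["placebo", "placebo", "drug"]))


class TestPerformanceRegression:
    def _cohort(self, rng, scaler_effect=-3.0, n=60):
        scaler = rng.random(n) < 0.5
        k1 = rng.uniform(0.3, 0.9, n)
        gamma = rng.uniform(0.1, 0.6, n)
        perf = (10 + scaler_effect * scaler - 2 * k1 + 1.5 * gamma
                + rng.normal(0, 1, n))
        return pd.DataFrame({
            "perf_error": perf,
            "nu": np.where(scaler, rng.uniform(0.3, 1, n), 0.0),
            "k1": k1, "gamma": gamma,
            "group": rng.choice(["placebo", "drug"], n),
        })

    def test_recovers_negative_scaler_effect(self):
        reg = performance_regression(self._cohort(np.random.default_rng(5)))
        assert reg.loc["scaler", "coef"] < 0
        assert reg.loc["scaler", "p"] < 0.01

    def test_null_cohort_pvalues_not_inflated(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(200):
            cohort = self._cohort(rng, scaler_effect=0.0, n=40)
            cohort["perf_error"] = rng.normal(0, 1, 40)
            reg = performance_regression(cohort)
            ps.append(reg.loc["scaler", "p"])
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.04

    def test_collinear_predictors_rejected(self):
        cohort = self._cohort(np.random.default_rng(7))
        cohort["gamma"] = cohort["k1"]
        with pytest.raises(ValueError):
            performance_regression(cohort)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            performance_regression(pd.DataFrame({"perf_error": [1.0]}))


class TestModelR2:
    def test_perfect_tracking_gives_unit_r2(self, ph2_agent):
        _, trials = ph2_agent
        ok = trials[~trials["missed"]]
        mu = ok.sort_values(["session", "trial"])["prediction"].to_numpy()
        assert model_r2(trials, mu) == pytest.approx(1.0)
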