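"""Learning models: recursions, nesting, boundedness, simulation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptpe import (
    ModelParams,
    ModelState,
    generate_experiment,
    model_step,
    predict_series,
    prediction_error,
    running_mean_agent,
    scale_pe,
    simulate_agent,
)

rates = st.floats(0.0, 1.0)
rewards_seq = st.lists(st.floats(0.0, 100.0), min_size=1, max_size=40)


def _roll(params, reward_seq, sd=10.0, mu0=50.0):
    """Fold model_step over a reward sequence, returning the mu trace."""
    state = ModelState(mu=mu0, k_current=params.k1
                       if params.model_id in ("PH1", "PH2") else 0.0)
    mus = []
    for r in reward_seq:
        state, mu = model_step(params, state, r, sd)
        mus.append(mu)
    return mus


class TestPredictionError:
    def test_sign_and_zero(self):
        assert prediction_error(40, 55) == 15
        assert prediction_error(55, 40) == -15
        assert prediction_error(35, 35) == 0

    def test_missing_propagates(self):
        assert math.isnan(prediction_error(float("nan"), 50))


class TestScalePe:
    def test_nu_zero_is_identity(self):
        assert scale_pe(10, 15, 0.0) == 10

    def test_unit_log_sd(self):
        assert scale_pe(10, math.e, 1.0) == pytest.approx(10.0)

    def test_hand_evaluated_example(self):
        assert scale_pe(10, 5, 1.0) == pytest.approx(10 / math.log(5),
                                                     abs=1e-4)

    def test_rejects_sd_at_or_below_one(self):
        with pytest.raises(ValueError):
            scale_pe(10, 1.0, 0.5)


class TestModelStep:
    def test_rw1_arithmetic(self):
        p = ModelParams(model_id="RW1", k=0.3)
        _, mu = model_step(p, ModelState(mu=50), 60, 10)
        assert mu == pytest.approx(53.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(k=rates, seq=rewards_seq)
    def test_rw2_equal_rates_reproduces_rw1(self, k, seq):
        rw1 = ModelParams(model_id="RW1", k=k)
        rw2 = ModelParams(model_id="RW2", k_pos=k, k_neg=k)
        assert _roll(rw1, seq) == _roll(rw2, seq)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(k1=rates, gamma=rates, seq=rewards_seq)
    def test_ph2_nu_zero_reproduces_ph1(self, k1, gamma, seq):
        ph1 = ModelParams(model_id="PH1", k1=k1, gamma=gamma)
        ph2 = ModelParams(model_id="PH2", k1=k1, gamma=gamma, nu=0.0)
        assert _roll(ph1, seq) == _roll(ph2, seq)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(k1=rates, gamma=rates, nu=rates, seq=rewards_seq)
    def test_mu_stays_on_scale(self, k1, gamma, nu, seq):
        p = ModelParams(model_id="PH2", k1=k1, gamma=gamma, nu=nu)
        assert all(0.0 <= mu <= 100.0 for mu in _roll(p, seq, sd=5.0))

    def test_ph2_update_dampened_more_at_larger_sd(self):
        """For the same PE, the adaptive model updates less under SD15
        than SD5 (scaling restrains learning when PEs fluctuate more)."""
        p = ModelParams(model_id="PH2", k1=0.5, gamma=0.3, nu=0.8)
        for delta in (5.0, -12.0, 30.0):
            steps = {}
            for sd in (5.0, 15.0):
                state = ModelState(mu=50.0, k_current=p.k1)
                new = model_step(p, state, 50.0 + delta, sd)[0]
                steps[sd] = abs(new.mu - 50.0)
            assert steps[15.0] < steps[5.0]

    def test_ph1_stabilizes_on_constant_rewards(self):
        """On a constant reward stream the PH rate decays with the shrinking
        |PE| and the prediction creeps to the reward (at an O(1/n) rate,
        since the rate itself is proportional to the remaining |PE|)."""
        p = ModelParams(model_id="PH1", k1=0.8, gamma=0.4)
        state = ModelState(mu=20.0, k_current=p.k1)
        gaps = []
        for i in range(20_000):
            state, _ = model_step(p, state, 70.0, 10.0)
            if i % 1000 == 0:
                gaps.append(abs(70.0 - state.mu))
        assert state.mu == pytest.approx(70.0, abs=0.01)
        assert state.k_current < 1e-3
        assert all(a >= b for a, b in zip(gaps, gaps[1:]))  # monotone approach

    def test_ph1_rate_mean_below_k1_on_iid_rewards(self):
        """On i.i.d. rewards the PH learning rate settles well below its
        initial value when gamma < 1 (|delta|/100 is small)."""
        p = ModelParams(model_id="PH1", k1=0.9, gamma=0.3)
        rng = np.random.default_rng(0)
        state = ModelState(mu=50.0, k_current=p.k1)
        ks = []
        for r in rng.normal(50, 10, size=500):
            state, _ = model_step(p, state, float(np.clip(r, 0, 100)), 10.0)
            ks.append(state.k_current)
        assert np.mean(ks[100:]) < p.k1


class TestPredictSeries:
    def test_no_learning_keeps_initial_mean(self, default_design):
        p = ModelParams(model_id="RW1", k=0.0)
        mus = predict_series(p, default_design.assign(prediction=50.0),
                             mu_init=50.0)
        assert (mus == 50.0).all()

    def test_full_learning_tracks_previous_reward(self, default_design):
        p = ModelParams(model_id="RW1", k=1.0)
        t = default_design.assign(prediction=50.0)
        mus = predict_series(p, t, mu_init=50.0)
        ordered = t.sort_values(["session", "trial"])
        # direct oracle: with k=1 the next mean is the pot's last reward
        states = {}
        expect = []
        for row in ordered.itertuples(index=False):
            mu = states.get(row.dist_id, 50.0)
            expect.append(mu)
            states[row.dist_id] = row.reward  # k=1: next mu is last reward
        assert np.allclose(mus, expect)

    def test_requires_sorted_input(self, default_design):
        p = ModelParams(model_id="RW1", k=0.5)
        shuffled = default_design.assign(prediction=50.0).sample(
            frac=1, random_state=0)
        with pytest.raises(ValueError):
            predict_series(p, shuffled, mu_init=50.0)


class TestSimulateAgent:
    def test_zero_noise_zero_learning_is_constant(self, default_design):
        p = ModelParams(model_id="RW1", k=0.0, sigma=1e-9)
        out = simulate_agent(p, default_design, np.random.default_rng(0))
        assert (out["prediction"] == 50.0).all()

    def test_same_seed_identical(self, default_design):
        p = ModelParams(model_id="PH2", k1=0.6, gamma=0.3, nu=0.5, sigma=3)
        a = simulate_agent(p, default_design, np.random.default_rng(9))
        b = simulate_agent(p, default_design, np.random.default_rng(9))
        assert a.equals(b)

    def test_pe_and_payoff_completed(self, ph2_agent):
        _, t = ph2_agent
        ok = t[~t["missed"]]
        assert np.allclose(ok["pe"], ok["reward"] - ok["prediction"])
        assert (ok["payoff"] >= 0).all()
        controls = ok[ok["is_control"]]
        assert set(controls["payoff"]).issubset({2.5, 5.0, 7.5})

    def test_miss_probability_marks_rows_missing(self, default_design):
        p = ModelParams(model_id="RW1", k=0.4, sigma=2)
        out = simulate_agent(p, default_design, np.random.default_rng(4),
                             miss_probability=0.3)
        missed = out[out["missed"]]
        assert len(missed) > 10
        assert missed["prediction"].isna().all()
        assert missed["reward"].isna().all()
        assert missed["pe"].isna().all()
        assert (missed["payoff"] == 0).all()

    def test_emitted_mean_converges_to_latent_mean(self, default_design):
        """Monte-Carlo: averaging emitted predictions over many agents
        recovers the noise-free latent mean at every trial position."""
        p = ModelParams(model_id="RW1", k=0.4, sigma=3)
        noise_free = simulate_agent(
            ModelParams(model_id="RW1", k=0.4, sigma=1e-12),
            default_design, np.random.default_rng(0))
        acc = np.zeros(len(default_design))
        n_agents = 300
        for i in range(n_agents):
            out = simulate_agent(p, default_design,
                                 np.random.default_rng(1000 + i))
            acc += out["prediction"].to_numpy()
        mean_pred = acc / n_agents
        # 300 agents, sigma 3: tolerate ~5 standard errors plus feedback
        assert np.abs(mean_pred - noise_free["prediction"].to_numpy()
                      ).max() < 1.5


class TestRunningMeanAgent:
    def test_predictions_are_running_means(self, default_design):
        out = running_mean_agent(default_design)
        ordered = out.sort_values(["session", "trial"])
        for dist_id, sub in ordered.groupby("dist_id", sort=False):
            r = sub["reward"].to_numpy()
            y = sub["prediction"].to_numpy()
            assert y[0] == 50.0
            expected = np.cumsum(r)[:-1] / np.arange(1, len(r))
            assert np.allclose(y[1:], expected)
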