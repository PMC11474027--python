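"""Beta-distribution trial-value model, gamma fitting, RPE regressions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cinda.synth import BehaviorSpec, gen_behavior
from cinda.value_model import (
    beta_value_series,
    fit_gamma,
    tonic_value_analysis,
    value_regression,
)
from conftest import homogeneous_train


class TestBetaValueSeries:
    def test_laplace_running_mean_at_gamma_one(self):
        vs = beta_value_series(np.array([1, 1, 1]), gamma=1.0)
        # after the third rewarded outcome: V = (1 + 3)/(2 + 3)
        assert vs.V_post[-1] == pytest.approx(4.0 / 5.0)

    def test_hand_computed_decay_sequence(self):
        vs = beta_value_series(np.array([1, 0]), gamma=0.5)
        np.testing.assert_allclose(vs.alpha, [1.0, 1.5])
        np.testing.assert_allclose(vs.beta, [1.0, 0.5])
        np.testing.assert_allclose(vs.V, [0.5, 0.75])
        assert vs.V_post[-1] == pytest.approx(0.375)  # (0.75)/(0.75+1.25)

    def test_converges_to_stationary_probability(self):
        rng = np.random.default_rng(0)
        outcomes = (rng.random(10_000) < 0.7).astype(int)
        vs = beta_value_series(outcomes, gamma=1.0)
        assert vs.V[-1] == pytest.approx(0.7, abs=0.02)

    @given(st.lists(st.integers(0, 1), min_size=3, max_size=40),
           st.floats(0.3, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_gamma_one_closed_form_and_reward_monotonicity(self, outcomes,
                                                           gamma):
        outcomes = np.array(outcomes)
        vs1 = beta_value_series(outcomes, gamma=1.0)
        t = np.arange(outcomes.size)
        closed = (1.0 + np.concatenate([[0], np.cumsum(outcomes)[:-1]])) / (
            2.0 + t
        )
        np.testing.assert_allclose(vs1.V, closed, rtol=1e-12)
        # flipping any 0 -> 1 weakly increases all subsequent V
        zeros = np.flatnonzero(outcomes == 0)
        if zeros.size:
            k = zeros[0]
            flipped = outcomes.copy()
            flipped[k] = 1
            v_f = beta_value_series(flipped, gamma=gamma).V
            v_0 = beta_value_series(outcomes, gamma=gamma).V
            assert np.all(v_f[k + 1:] >= v_0[k + 1:] - 1e-12)
            np.testing.assert_allclose(v_f[: k + 1], v_0[: k + 1])

    def test_terciles_partition_in_thirds(self):
        rng = np.random.default_rng(1)
        vs = beta_value_series((rng.random(90) < 0.5).astype(int), 0.8)
        counts = {lab: np.sum(vs.tercile == lab)
                  for lab in ("low", "med", "high")}
        assert all(c == 30 for c in counts.values())
        assert vs.V[vs.tercile == "high"].min() >= vs.V[
            vs.tercile == "low"
        ].max() - 1e-12

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            beta_value_series(np.array([1, 0]), gamma=0.0)


class TestFitGamma:
    def test_perfect_coupling_gives_r_minus_one_at_true_gamma(self):
        rng = np.random.default_rng(2)
        outcomes = (rng.random(400) < 0.5).astype(int)
        vs = beta_value_series(outcomes, gamma=0.8)
        import pandas as pd

        trials = pd.DataFrame({"outcome": outcomes,
                               "latency": np.exp(-vs.V)})
        gamma_star, profile = fit_gamma(trials)
        assert gamma_star == pytest.approx(0.8, abs=1e-9)
        r_at_true = profile.loc[
            np.isclose(profile["gamma"], 0.8), "r"
        ].iloc[0]
        assert r_at_true == pytest.approx(-1.0, abs=1e-9)

    def test_recovery_from_generated_behavior(self):
        hits = 0
        for seed in range(10):
            trials, _ = gen_behavior(
                BehaviorSpec(n_blocks=30, gamma_true=0.7), seed=seed,
                n_trials=1_000,
            )
            gamma_star, _ = fit_gamma(trials)
            hits += abs(gamma_star - 0.7) <= 0.05
        assert hits >= 8

    def test_constant_latency_rejected(self):
        import pandas as pd

        trials = pd.DataFrame({"outcome": [1, 0] * 20,
                               "latency": np.ones(40)})
        with pytest.raises(ValueError, match="latency"):
            fit_gamma(trials)


class TestValueRegression:
    def make_values(self, n=300, seed=3):
        trials, gt = gen_behavior(BehaviorSpec(n_blocks=9), seed=seed,
                                  n_trials=n)
        return trials, beta_value_series(trials, 0.7)

    def test_known_slope_recovered(self):
        trials, values = self.make_values()
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(20):
            rates = 10.0 - 5.0 * values.V + rng.normal(0, 1, len(values))
            rr = value_regression(rates, values, scope="epoch")
            ok = (-6.0 <= rr.coefficient <= -4.0 and rr.p_value < 0.01
                  and rr.sign == "negative")
            hits += ok
        assert hits >= 19

    def test_null_signal_calibrated(self):
        trials, values = self.make_values()
        rng = np.random.default_rng(5)
        sig = 0
        n_rep = 400
        for _ in range(n_rep):
            rates = rng.normal(5.0, 1.0, len(values))
            sig += value_regression(rates, values, scope="epoch",
                                    alpha=0.05).significant
        assert sig / n_rep == pytest.approx(0.05, abs=0.025)

    def test_constant_signal_convention(self):
        trials, values = self.make_values()
        rr = value_regression(np.full(len(values), 3.0), values,
                              scope="epoch")
        assert rr.coefficient == 0.0 and rr.p_value == 1.0

    def test_per_bin_scope_with_bonferroni(self):
        trials, values = self.make_values()
        rng = np.random.default_rng(6)
        n_bins = 20
        mat = rng.normal(5.0, 1.0, (len(values), n_bins))
        mat[:, 7] += 8.0 * values.V  # one value-coding bin
        rr = value_regression(mat, values, scope="per_bin", alpha=0.05)
        assert rr.significant[7]
        assert rr.significant.sum() <= 2

    def test_zero_value_variance_rejected(self):
        trials, values = self.make_values()
        values.V[:] = 0.5
        with pytest.raises(ValueError, match="value not identified"):
            value_regression(np.ones(len(values)), values, scope="epoch")


class TestTonicAnalysis:
    def test_minute_bins_count(self):
        import pandas as pd

        trials = pd.DataFrame(
            {"light_on": [10.0, 30.0], "side_in": [15.0, 35.0]}
        )
        vs = beta_value_series(np.array([1, 0]), 0.9)
        res = tonic_value_analysis(np.array([1.0, 2.0, 20.0]), trials, vs,
                                   duration=60.0)
        assert res["minute_rates"].size == 1

    def test_value_coding_rate_detected(self):
        trials, gt = gen_behavior(BehaviorSpec(n_blocks=9), seed=7,
                                  n_trials=300)
        dur = float(trials["side_in"].max()) + 10.0
        vs = beta_value_series(trials, 0.7)
        # rate scales with V: draw ITI spikes at rate 4 + 2 V per trial
        rng = np.random.default_rng(8)
        spikes = []
        for lo, v in zip(trials["light_on"], vs.V):
            n = rng.poisson(3.0 * (4.0 + 2.0 * v))
            spikes.append(rng.uniform(lo - 3.0, lo, n))
        st_all = np.sort(np.concatenate(spikes))
        res = tonic_value_analysis(st_all, trials, vs, duration=dur)
        assert res["tercile_means"]["high"] > res["tercile_means"]["low"]
        assert res["kruskal_p"] < 0.05

    def test_null_unit_terciles_indistinguishable(self):
        trials, _ = gen_behavior(BehaviorSpec(n_blocks=9), seed=9,
                                 n_trials=300)
        dur = float(trials["side_in"].max()) + 10.0
        st_all = homogeneous_train(5.0, 1.0, dur, seed=10)
        vs = beta_value_series(trials, 0.7)
        res = tonic_value_analysis(st_all, trials, vs, duration=dur)
        assert res["kruskal_p"] > 0.01
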