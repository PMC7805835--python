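"""Unit and property tests for the CTRNN state representation and
forward-Euler integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctrnn_selfopt import (
    NetworkState,
    NodeParams,
    WeightMatrix,
    compute_bias,
    derivative,
    euler_step,
    node_outputs,
    relax,
    relax_batch,
    sigmoid,
)
from ctrnn_selfopt.ctrnn_core import FIXED_POINT_TOL

from conftest import make_toy_params


class TestSigmoid:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (0.0, 0.0),
            (math.log(3.0), 0.5),   # solve 2/(1+e^-x) - 1 = 1/2
            (-math.log(3.0), -0.5),
            (50.0, 1.0),            # asymptote
            (-50.0, -1.0),
        ],
    )
    def test_values(self, x, expected):
        assert sigmoid(x) == pytest.approx(expected, abs=1e-12)

    def test_matches_closed_form(self, rng):
        x = rng.normal(scale=5.0, size=1000)
        np.testing.assert_allclose(sigmoid(x), 2.0 / (1.0 + np.exp(-x)) - 1.0,
                                   atol=1e-14)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-700, max_value=700))
    def test_odd_and_bounded(self, x):
        y = sigmoid(x)
        assert -1.0 <= y <= 1.0
        assert sigmoid(-x) == pytest.approx(-y, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-15, max_value=15))
    def test_strictly_increasing_away_from_saturation(self, x):
        # strictness is only resolvable in floats before the tails saturate
        assert sigmoid(x + 1e-2) > sigmoid(x)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            sigmoid(float("nan"))
        with pytest.raises(ValueError):
            sigmoid(np.array([1.0, np.inf]))


class TestBiasAndOutputs:
    def test_zero_weights_zero_bias(self):
        W = WeightMatrix(np.zeros((4, 4)))
        assert np.all(compute_bias(W) == 0.0)

    def test_bias_is_negative_half_row_sum(self, rng):
        W = WeightMatrix(rng.normal(size=(6, 6)))
        np.testing.assert_allclose(compute_bias(W), -0.5 * W.values.sum(axis=1))

    def test_two_node_example(self):
        W = WeightMatrix(np.array([[1.0, 1.0], [0.0, 0.0]]))
        np.testing.assert_allclose(compute_bias(W), [-1.0, 0.0])

    def test_output_zero_where_activation_cancels_bias(self):
        params = NodeParams(tau=np.ones(3), gain=np.array([10.0, 20.0, 15.0]),
                            bias=np.array([1.0, -2.0, 0.5]))
        V = node_outputs(-params.bias, params)
        np.testing.assert_allclose(V, 0.0, atol=1e-15)

    def test_high_gain_saturates(self):
        params = NodeParams(tau=np.ones(2), gain=np.array([500.0, 500.0]),
                            bias=np.zeros(2))
        V = node_outputs(np.array([0.5, -0.5]), params)
        np.testing.assert_allclose(V, [1.0, -1.0], atol=1e-12)


class TestDerivativeAndStep:
    def test_pure_decay(self):
        W = WeightMatrix(np.zeros((1, 1)))
        params = make_toy_params(W, tau=1.0)
        state = NetworkState.from_activations([1.0], params)
        assert derivative(state, W, params) == pytest.approx([-1.0])

    def test_zero_at_fixed_point(self):
        # fixed point: s* = V(s*) @ W; construct one by hand for W = 0, s = 0
        W = WeightMatrix(np.zeros((3, 3)))
        params = make_toy_params(W)
        state = NetworkState.from_activations(np.zeros(3), params)
        np.testing.assert_allclose(derivative(state, W, params), 0.0)

    @pytest.mark.parametrize("mode", ["synchronous", "asynchronous"])
    def test_single_decay_step(self, mode, rng):
        W = WeightMatrix(np.zeros((1, 1)))
        params = make_toy_params(W, tau=1.0, dt=0.1)
        state = NetworkState.from_activations([1.0], params)
        out = euler_step(state, W, params, mode=mode, rng=rng)
        assert out.s[0] == pytest.approx(0.9)

    @pytest.mark.parametrize("mode", ["synchronous", "asynchronous"])
    def test_zero_derivative_leaves_state_unchanged(self, mode, rng):
        W = WeightMatrix(np.zeros((4, 4)))
        params = make_toy_params(W)
        state = NetworkState.from_activations(np.zeros(4), params)
        out = euler_step(state, W, params, mode=mode, rng=rng)
        np.testing.assert_array_equal(out.s, state.s)

    def test_modes_agree_as_dt_shrinks(self, rng):
        # on a seeded 5-node net the sync/async endpoint gap shrinks with dt
        W = WeightMatrix(np.random.default_rng(3).normal(scale=0.3, size=(5, 5)))
        s0 = np.random.default_rng(4).uniform(-1, 1, size=5)
        gaps = []
        for dt in (0.1, 0.01):
            ends = {}
            for mode in ("synchronous", "asynchronous"):
                params = make_toy_params(W, tau=1.0, gain=2.0, dt=dt, duration=10.0)
                state = NetworkState.from_activations(s0, params)
                for _ in range(params.n_steps):
                    state = euler_step(state, W, params, mode=mode, rng=rng)
                ends[mode] = state.s
            gaps.append(np.max(np.abs(ends["synchronous"] - ends["asynchronous"])))
        assert gaps[1] < gaps[0]
        assert gaps[1] < 1e-3

    def test_unstable_dt_rejected_at_construction(self):
        with pytest.raises(ValueError, match="unstable"):
            NodeParams(tau=np.full(3, 0.04), gain=np.ones(3), bias=np.zeros(3),
                       dt=0.1)


class TestEulerAccuracy:
    def test_single_node_matches_exponential_decay(self):
        # zero weights: ds/dt = -s/tau, closed form s(t) = s0 exp(-t/tau)
        W = WeightMatrix(np.zeros((1, 1)))
        tau, s0 = 2.0, 1.5
        errors = {}
        for dt in (0.1, 0.05):
            params = make_toy_params(W, tau=tau, dt=dt, duration=10.0)
            state = NetworkState.from_activations([s0], params)
            worst = 0.0
            for k in range(1, params.n_steps + 1):
                state = euler_step(state, W, params, mode="synchronous")
                exact = s0 * math.exp(-k * dt / tau)
                worst = max(worst, abs(state.s[0] - exact))
            errors[dt] = worst
        assert errors[0.1] < 0.05 * s0          # first-order accurate at dt=0.1
        ratio = errors[0.1] / errors[0.05]
        assert 1.5 < ratio < 2.5                # halving dt halves the error

    @pytest.mark.parametrize("mode", ["synchronous", "asynchronous"])
    def test_kernel_endpoint_matches_closed_form(self, mode, rng):
        W = WeightMatrix(np.zeros((1, 1)))
        params = make_toy_params(W, tau=3.0, dt=0.1, duration=12.0)
        state = NetworkState.from_activations([2.0], params)
        rec = relax(state, W, params, mode=mode, rng=rng)
        # forward Euler at dt/tau = 1/30 over 120 steps carries ~7% relative
        # error at this horizon: (1 - dt/tau)^n vs exp(-n dt/tau)
        assert rec.final_s[0] == pytest.approx(2.0 * math.exp(-12.0 / 3.0), rel=0.1)


class TestRelax:
    def test_global_decay_converges_to_origin(self, rng):
        W = WeightMatrix(np.zeros((5, 5)))
        params = make_toy_params(W, duration=100.0)
        state = NetworkState.from_activations(rng.uniform(-5, 5, 5), params)
        rec = relax(state, W, params, rng=rng)
        assert rec.converged
        np.testing.assert_allclose(rec.final_s, 0.0, atol=1e-6)

    def test_step_count_is_floor_of_duration_over_dt(self):
        params = NodeParams(tau=np.ones(2), gain=np.ones(2), bias=np.zeros(2),
                            dt=0.1, duration=500.0)
        assert params.n_steps == 5000
        params = NodeParams(tau=np.ones(2), gain=np.ones(2), bias=np.zeros(2),
                            dt=0.3, duration=1.0)
        assert params.n_steps == 3

    def test_converged_flag_means_small_residual(self, rng):
        W = WeightMatrix(rng.normal(scale=0.2, size=(4, 4)))
        params = make_toy_params(W, gain=3.0, duration=200.0)
        state = NetworkState.from_activations(rng.uniform(-2, 2, 4), params)
        rec = relax(state, W, params, rng=rng)
        if rec.converged:
            final = NetworkState.from_activations(rec.final_s, params)
            assert np.max(np.abs(derivative(final, W, params))) < FIXED_POINT_TOL

    def test_kernel_agrees_with_python_stepper(self, rng):
        # synchronous kernel vs the pure-Python euler_step, step for step
        W = WeightMatrix(np.random.default_rng(9).normal(scale=0.4, size=(6, 6)))
        params = make_toy_params(W, tau=2.0, gain=4.0, dt=0.1, duration=5.0)
        s0 = np.random.default_rng(10).uniform(-2, 2, 6)
        state = NetworkState.from_activations(s0.copy(), params)
        for _ in range(params.n_steps):
            state = euler_step(state, W, params, mode="synchronous")
        rec = relax(NetworkState.from_activations(s0.copy(), params), W, params,
                    mode="synchronous", rng=rng)
        np.testing.assert_allclose(rec.final_s, state.s, atol=1e-12)

    def test_batch_matches_individual_relaxations(self, rng):
        W = WeightMatrix(np.random.default_rng(2).normal(scale=0.3, size=(4, 4)))
        params = make_toy_params(W, duration=20.0)
        S0 = np.random.default_rng(5).uniform(-3, 3, size=(6, 4))
        batch = relax_batch(S0, W, params, mode="synchronous", rng=rng)
        for row, rec in zip(S0, batch):
            single = relax(NetworkState.from_activations(row, params), W, params,
                           mode="synchronous", rng=rng)
            np.testing.assert_allclose(rec.final_s, single.final_s, atol=1e-12)


class TestWeightMatrixIO:
    def test_csv_round_trip(self, tmp_path, rng):
        W = WeightMatrix(rng.normal(size=(5, 5)), role="original_alpha", seed=42)
        path = tmp_path / "w.csv"
        W.to_csv(path)
        back = WeightMatrix.from_csv(path)
        np.testing.assert_array_equal(back.values, W.values)
        assert back.role == "original_alpha"
        assert back.seed == 42

    def test_json_round_trip(self, tmp_path, rng):
        W = WeightMatrix(rng.normal(size=(3, 3)), role="current_omega")
        path = tmp_path / "w.json"
        W.to_json(path)
        back = WeightMatrix.from_json(path)
        np.testing.assert_array_equal(back.values, W.values)
        assert back.role == "current_omega"

    def test_rejects_non_square(self):
        with pytest.raises(ValueError, match="square"):
            WeightMatrix(np.zeros((2, 3)))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            WeightMatrix(np.array([[np.nan, 0.0], [0.0, 0.0]]))
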