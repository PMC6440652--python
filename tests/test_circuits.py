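"""Circuit models: input signals, right-hand sides, simulation contracts."""

import numpy as np
import pytest

from hsoed import (
    InputSignal,
    make_circuit,
    make_input,
    simulate_trajectory,
    unbuffered_rhs,
    buffered_rhs,
)
from hsoed.circuits import (
    BUFFERED_KINETIC,
    UNBUFFERED_KINETIC,
    initial_state,
)


class TestInputSignals:
    def test_step_holds_magnitude_after_onset(self):
        sig = make_input("step", 20.0)
        assert sig(10.0) == 20.0
        assert sig(0.0) == 20.0

    def test_step_before_onset_is_zero(self):
        sig = make_input("step", 20.0, onset=100.0)
        assert sig(50.0) == 0.0
        assert sig(100.0) == 20.0

    def test_square_is_high_first_half_period(self):
        sig = make_input("square", 20.0, period=100.0)
        assert sig(25.0) == 20.0
        assert sig(75.0) == 0.0
        assert sig(125.0) == 20.0

    def test_zero_magnitude_is_identically_zero(self):
        sig = make_input("step", 0.0)
        assert np.all(sig(np.linspace(0, 1000, 11)) == 0.0)

    def test_double_step_switches_level(self):
        sig = make_input("double_step", 10.0, second_onset=500.0,
                         second_magnitude=25.0)
        assert sig(100.0) == 10.0
        assert sig(600.0) == 25.0

    @pytest.mark.parametrize("kwargs", [
        dict(kind="square", magnitude=5.0, period=-1.0),
        dict(kind="square", magnitude=5.0),
        dict(kind="step", magnitude=-1.0),
        dict(kind="ramp", magnitude=1.0),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_input(**kwargs)

    def test_signal_finite_nonnegative_everywhere(self):
        for sig in (make_input("square", 20.0, period=137.0, onset=13.0),
                    make_input("double_step", 3.0, second_onset=10.0)):
            vals = sig(np.linspace(0, 5000, 499))
            assert np.all(np.isfinite(vals)) and np.all(vals >= 0)


class TestRightHandSides:
    def test_unbuffered_dimension_and_param_count(self, unbuffered):
        assert unbuffered.n_states == 3
        assert len(UNBUFFERED_KINETIC) == 9
        out = unbuffered_rhs(np.zeros(3), 0.0, unbuffered.kinetic_params,
                             unbuffered.fixed_constants, lambda t: 20.0)
        assert out.shape == (3,)

    def test_buffered_dimension_and_param_count(self, buffered):
        assert buffered.n_states == 10
        assert len(BUFFERED_KINETIC) == 23
        out = buffered_rhs(np.zeros(10), 0.0, buffered.kinetic_params,
                           buffered.fixed_constants, lambda t: 20.0)
        assert out.shape == (10,)

    def test_unbuffered_absorbing_zero_state(self, unbuffered):
        m = make_circuit("unbuffered", params={"k_sgfp": 0.0})
        out = unbuffered_rhs(np.zeros(3), 0.0, m.kinetic_params,
                             m.fixed_constants, lambda t: 0.0)
        assert np.all(out == 0.0)

    def test_buffered_absorbing_zero_state(self):
        m = make_circuit("buffered", params={"k_w": 0.0, "k_x": 0.0,
                                             "k_sgfp": 0.0, "r1": 0.0,
                                             "r2": 0.0})
        out = buffered_rhs(np.zeros(10), 0.0, m.kinetic_params,
                           m.fixed_constants, lambda t: 0.0)
        assert np.all(out == 0.0)

    @pytest.mark.parametrize("name", ["unbuffered", "buffered"])
    def test_rhs_matches_symbolic_mirror(self, name):
        """Numeric RHS agrees with an independently differentiable sympy copy."""
        import sympy as sp

        from hsoed._symbolic import symbolic_rhs

        model = make_circuit(name)
        states, params, fixed, u, load, f = symbolic_rhs(name)
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.uniform(0.1, 2.0, model.n_states)
            dox = rng.uniform(0.0, 30.0)
            subs = dict(zip(states, x))
            subs.update(zip(params, model.kinetic_params))
            subs.update(zip(fixed, model.fixed_constants))
            subs[u] = dox
            subs[load] = 1.0
            expected = np.array([float(sp.N(e.subs(subs))) for e in f])
            fn = unbuffered_rhs if name == "unbuffered" else buffered_rhs
            got = fn(x, 0.0, model.kinetic_params, model.fixed_constants,
                     lambda t: dox)
            np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_negative_parameters_rejected(self, unbuffered):
        bad = np.array(unbuffered.kinetic_params)
        bad[0] = -1.0
        with pytest.raises(ValueError):
            unbuffered_rhs(np.zeros(3), 0.0, bad, unbuffered.fixed_constants,
                           lambda t: 0.0)
        with pytest.raises(ValueError):
            unbuffered_rhs(np.array([np.nan, 0, 0]), 0.0,
                           unbuffered.kinetic_params,
                           unbuffered.fixed_constants, lambda t: 0.0)


class TestModelConstruction:
    def test_buffered_phosphotransfer_ordering_enforced(self):
        with pytest.raises(ValueError, match="k1"):
            make_circuit("buffered", params={"k1": 2.0, "k3": 5.0})
        with pytest.raises(ValueError, match="50"):
            make_circuit("buffered", params={"k2": 60.0})

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            make_circuit("unbuffered", params={"nope": 1.0})

    def test_load_factor_scales_promoter_pool(self):
        """With more load sites the bound-complex pool can grow larger."""
        t = np.linspace(0, 2000, 41)
        inp = make_input("step", 20.0)
        c1 = simulate_trajectory(make_circuit("unbuffered"), inp, t)
        c3 = simulate_trajectory(make_circuit("unbuffered", load_factor=3.0),
                                 inp, t)
        assert c3.states[:, 1].max() > c1.states[:, 1].max()


class TestSimulation:
    def test_zero_everything_stays_zero(self):
        m = make_circuit("unbuffered", params={"k_sgfp": 0.0})
        traj = simulate_trajectory(m, make_input("step", 0.0),
                                   np.linspace(0, 500, 11))
        assert np.all(traj.states == 0.0)

    def test_decoupled_reporter_matches_linear_closed_form(self):
        """Zero input decouples the reporter equation into a linear ODE with
        exact solution G(t) = (k_sgfp/δ_G)(1 − exp(−δ_G t)); the solver must
        reproduce it to 1e-6 relative."""
        m = make_circuit("unbuffered")
        p = m.params_dict()
        t = np.linspace(0, 2000, 41)
        traj = simulate_trajectory(m, make_input("step", 0.0), t)
        expected = p["k_sgfp"] / p["delta_G"] * (1 - np.exp(-p["delta_G"] * t))
        np.testing.assert_allclose(traj.observable(2), expected, rtol=1e-6,
                                   atol=1e-10)

    def test_steady_baseline_limit(self):
        """Zero input, long horizon: Ĝ → k_sgfp/δ_G within 1%."""
        m = make_circuit("unbuffered")
        p = m.params_dict()
        traj = simulate_trajectory(m, make_input("step", 0.0),
                                   np.linspace(0, 3000, 31))
        assert traj.observable(2)[-1] == pytest.approx(
            p["k_sgfp"] / p["delta_G"], rel=0.01)

    @pytest.mark.parametrize("name", ["unbuffered", "buffered"])
    def test_non_negativity_under_step(self, name):
        atol = 1e-10
        traj = simulate_trajectory(make_circuit(name), make_input("step", 20.0),
                                   np.linspace(0, 3000, 61), atol=atol)
        assert traj.states.min() >= -atol
        assert np.all(np.isfinite(traj.states))

    def test_complex_bounded_by_promoter_pool(self, unbuffered, step20):
        p = unbuffered.params_dict()
        traj = simulate_trajectory(unbuffered, step20,
                                   np.linspace(0, 3000, 61))
        assert traj.states[:, 1].max() <= p["p_T"] + 1e-8

    def test_solver_tolerance_contract(self, unbuffered, step20):
        """Halving rtol changes the GFP trajectory by < 1e-6 relative."""
        t = np.linspace(0, 3000, 31)
        a = simulate_trajectory(unbuffered, step20, t, rtol=1e-8).observable(2)
        b = simulate_trajectory(unbuffered, step20, t, rtol=5e-9).observable(2)
        assert np.max(np.abs(a - b)) / np.max(np.abs(a)) < 1e-6

    def test_buffered_step_response_settles(self, buffered, step20):
        traj = simulate_trajectory(buffered, step20, np.linspace(0, 3000, 61))
        g = traj.observable(9)
        assert np.all(np.isfinite(traj.states))
        assert abs(g[-1] - g[-2]) < 1e-3 * abs(g[-1])

    def test_square_wave_oscillates_reporter(self, unbuffered):
        inp = make_input("square", 20.0, period=400.0)
        t = np.linspace(0, 3000, 301)
        g = simulate_trajectory(unbuffered, inp, t).observable(2)
        late = g[t > 1000]
        assert late.max() - late.min() > 0.05 * late.max()

    def test_bad_time_grids_rejected(self, unbuffered, step20):
        with pytest.raises(ValueError):
            simulate_trajectory(unbuffered, step20, [1.0, 2.0])
        with pytest.raises(ValueError):
            simulate_trajectory(unbuffered, step20, [0.0, 2.0, 2.0])

    def test_trajectory_csv_roundtrip(self, unbuffered, step20, tmp_path):
        import pandas as pd

        traj = simulate_trajectory(unbuffered, step20, np.linspace(0, 100, 6))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time", "X_m", "C_m", "G", "input"]
        np.testing.assert_allclose(df["G"].to_numpy(), traj.observable(2))

    def test_buffered_initial_pools_at_steady_state(self, buffered):
        p = buffered.params_dict()
        x0 = initial_state(buffered)
        assert x0[2] == pytest.approx(p["k_w"] / p["delta_W"])
        assert x0[4] == pytest.approx(p["k_x"] / p["delta_X"])
        assert np.all(x0[[0, 1, 3, 5, 6, 7, 8, 9]] == 0.0)
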