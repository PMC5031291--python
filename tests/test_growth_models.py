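import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from cellphenofit.growth_models import (
    InvalidInputError,
    UndefinedDoublingError,
    doubling_time,
    get_model,
    model_registry,
    simulate_exponential,
    simulate_live_dead,
    simulate_live_dead_logistic,
    simulate_logistic,
    simulate_model,
)


class TestExponential:
    def test_zero_rate_is_identity(self):
        traj = simulate_exponential(1.0, 0.0, [0, 5, 10])
        np.testing.assert_array_equal(traj.values["Live"], [1, 1, 1])

    def test_population_doubles_at_doubling_time(self):
        # rate 0.397/h corresponds to a 1.75 h doubling time
        traj = simulate_exponential(1.0, 0.397, [0.0, 1.75])
        assert traj.values["Live"][-1] == pytest.approx(2.0, rel=5e-3)

    def test_closed_form_value(self):
        traj = simulate_exponential(50.0, 0.0354, [0.0, 24.0])
        assert traj.values["Live"][-1] == pytest.approx(50 * math.exp(0.8496))
        assert traj.values["Live"][-1] == pytest.approx(116.9, abs=0.05)

    @pytest.mark.parametrize("times", [[], [1.0, 1.0], [2.0, 1.0]])
    def test_bad_time_grids_rejected(self, times):
        with pytest.raises(InvalidInputError):
            simulate_exponential(1.0, 0.1, times)

    @pytest.mark.parametrize("rate,trend", [(0.1, 1), (0.0, 0), (-0.1, -1)])
    def test_monotonicity_follows_rate_sign(self, rate, trend):
        traj = simulate_exponential(100.0, rate, np.linspace(0, 50, 20))
        diffs = np.diff(traj.values["Live"])
        if trend > 0:
            assert np.all(diffs > 0)
        elif trend < 0:
            assert np.all(diffs < 0)
        else:
            assert np.all(diffs == 0)


class TestLogistic:
    def test_carrying_capacity_is_fixed_point(self):
        traj = simulate_logistic(1000.0, 0.3, 1000.0, [0, 10, 20])
        np.testing.assert_allclose(traj.values["Live"], 1000.0)

    def test_closed_form_value(self):
        # N0=100, r=ln 3, cap=1000 at t=1: 1000/(1+9/3) = 250
        traj = simulate_logistic(100.0, math.log(3), 1000.0, [0.0, 1.0])
        assert traj.values["Live"][-1] == pytest.approx(250.0)

    def test_infinite_cap_limit_is_exponential(self):
        t = np.linspace(0, 10, 11)
        log_traj = simulate_logistic(1.0, 0.1, 1e12, t)
        exp_traj = simulate_exponential(1.0, 0.1, t)
        np.testing.assert_allclose(log_traj.values["Live"],
                                   exp_traj.values["Live"], rtol=1e-9)

    def test_nonpositive_cap_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_logistic(10.0, 0.1, 0.0, [0, 1])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(n0=st.floats(1.0, 1e5), r=st.floats(0.0, 0.5),
           cap=st.floats(1.0, 1e6))
    def test_growing_trajectories_bounded_between_start_and_cap(self, n0, r, cap):
        traj = simulate_logistic(n0, r, cap, np.linspace(0, 100, 23))
        vals = traj.values["Live"]
        lo, hi = min(n0, cap), max(n0, cap)
        assert np.all(vals >= lo * (1 - 1e-12))
        assert np.all(vals <= hi * (1 + 1e-12))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(frac=st.floats(1e-6, 1.0), r=st.floats(-0.5, 0.0),
           cap=st.floats(1.0, 1e6))
    def test_shrinking_subcapacity_trajectories_stay_nonnegative(self, frac, r, cap):
        # below capacity with r < 0 the culture decays towards zero,
        # below min(N0, cap) but never negative (above capacity with
        # r < 0 the logistic equation diverges in finite time)
        n0 = frac * cap
        vals = simulate_logistic(n0, r, cap, np.linspace(0, 100, 23)).values["Live"]
        assert np.all(vals >= 0)
        assert np.all(vals <= max(n0, cap) * (1 + 1e-12))


class TestLiveDead:
    def test_dead_compartment_decouples_without_death(self):
        traj = simulate_live_dead(100.0, 30.0, 0.05, 0.0, 0.0, [0, 10, 20])
        np.testing.assert_allclose(traj.values["Dead"], 30.0)
        exp = simulate_exponential(100.0, 0.05, [0, 10, 20])
        np.testing.assert_allclose(traj.values["Live"], exp.values["Live"])

    def test_degenerate_balance_gives_linear_dead_accumulation(self):
        # b = d, c = 0: live constant, dead grows as d*L0*t
        traj = simulate_live_dead(100.0, 0.0, 0.1, 0.1, 0.0, [0.0, 1.0, 2.0])
        np.testing.assert_allclose(traj.values["Live"], 100.0)
        np.testing.assert_allclose(traj.values["Dead"], [0.0, 10.0, 20.0])

    def test_matches_runge_kutta_oracle(self):
        b, d, c, l0, d0 = 0.04, 0.01, 0.005, 1000.0, 50.0
        t = np.linspace(0, 72, 13)
        traj = simulate_live_dead(l0, d0, b, d, c, t)
        sol = solve_ivp(
            lambda _t, y: [(b - d) * y[0], d * y[0] - c * y[1]],
            (0, 72), [l0, d0], t_eval=t, rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(traj.values["Live"], sol.y[0], rtol=1e-6)
        np.testing.assert_allclose(traj.values["Dead"], sol.y[1], rtol=1e-6)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_live_dead(100.0, 0.0, 0.05, -0.01, 0.0, [0, 1])
        with pytest.raises(InvalidInputError):
            simulate_live_dead(-1.0, 0.0, 0.05, 0.01, 0.0, [0, 1])


class TestLiveDeadLogistic:
    def test_reduces_to_logistic_without_death(self):
        t = np.linspace(0, 72, 10)
        traj = simulate_live_dead_logistic(500.0, 20.0, 0.08, 0.0, 0.0,
                                           10000.0, t)
        ref = simulate_logistic(500.0, 0.08, 10000.0, t)
        np.testing.assert_allclose(traj.values["Live"], ref.values["Live"],
                                   rtol=1e-6)

    def test_infinite_cap_limit_matches_live_dead(self):
        t = np.linspace(0, 72, 10)
        traj = simulate_live_dead_logistic(500.0, 20.0, 0.05, 0.01, 0.02,
                                           1e12, t)
        ref = simulate_live_dead(500.0, 20.0, 0.05, 0.01, 0.02, t)
        for obs in ("Live", "Dead"):
            np.testing.assert_allclose(traj.values[obs], ref.values[obs],
                                       rtol=1e-6)

    def test_step_halving_convergence(self):
        # independent fixed-step RK4 at two resolutions brackets the
        # adaptive solution
        b, d, c, cap = 0.08, 0.015, 0.02, 8000.0
        t = np.linspace(0, 72, 7)
        traj = simulate_live_dead_logistic(800.0, 40.0, b, d, c, cap, t)

        def rk4(n_steps):
            y = np.array([800.0, 40.0])
            f = lambda y: np.array([b * (1 - y[0] / cap) * y[0] - d * y[0],
                                    d * y[0] - c * y[1]])
            out, grid = [y.copy()], np.linspace(0, 72, n_steps + 1)
            h = grid[1] - grid[0]
            for _ in range(n_steps):
                k1 = f(y); k2 = f(y + h / 2 * k1)
                k3 = f(y + h / 2 * k2); k4 = f(y + h * k3)
                y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                out.append(y.copy())
            return grid, np.array(out)

        grid, ref = rk4(720)
        idx = [np.argmin(np.abs(grid - ti)) for ti in t]
        np.testing.assert_allclose(traj.values["Live"], ref[idx, 0], rtol=1e-6)
        np.testing.assert_allclose(traj.values["Dead"], ref[idx, 1], rtol=1e-6)


class TestRegistry:
    def test_six_models_with_expected_parameter_counts(self):
        registry = model_registry()
        assert len(registry) == 6
        counts = {s.name: s.n_parameters for s in registry}
        assert counts == {"live": 2, "live_logistic": 3, "live_dead": 5,
                          "live_dead_logistic": 6, "total": 2,
                          "total_logistic": 3}

    def test_registry_consistency(self):
        registry = model_registry()
        assert len({s.name for s in registry}) == 6
        assert get_model("total").observables == ("Total",)
        for s in registry:
            assert s.n_parameters == len(s.parameter_names)
            assert s.description

    def test_simulate_model_dispatch_covers_registry(self):
        defaults = {"growth_rate": 0.05, "birth_rate": 0.05, "death_rate": 0.01,
                    "clearance_rate": 0.01, "L_cap": 1e4, "T_cap": 1e4,
                    "initial_live": 100.0, "initial_dead": 5.0,
                    "initial_total": 105.0}
        for spec in model_registry():
            traj = simulate_model(spec, defaults, [0.0, 24.0])
            assert set(traj.values) == set(spec.observables)
            for vals in traj.values.values():
                assert np.all(vals >= 0)


class TestDoublingTime:
    def test_unit_rate(self):
        assert doubling_time(math.log(2)) == pytest.approx(1.0)

    def test_printed_anchor_value(self):
        assert doubling_time(0.397) == pytest.approx(1.75, abs=0.005)

    def test_hand_computed_value(self):
        assert doubling_time(0.0354) == pytest.approx(19.6, abs=0.05)

    @pytest.mark.parametrize("rate", [0.0, -0.1])
    def test_nonpositive_rate_rejected(self, rate):
        with pytest.raises(UndefinedDoublingError):
            doubling_time(rate)
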