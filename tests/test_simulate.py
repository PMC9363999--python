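"""State, current and sensitivity simulation against analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbamkit import (
    CurrentTrace,
    KineticModel,
    MeasurementSchedule,
    Parameter,
    ParameterVector,
    SimulationError,
    SolverOptions,
    VoltageProtocol,
    read_trace_csv,
    simulate_current,
    simulate_sensitivities,
    simulate_states,
    steady_state,
    uniform_schedule,
    write_trace_csv,
)
from mbamkit.models import Transition
from mbamkit.simulate import ODE_SOLVER


def two_state_model(extra_param=False):
    """C <-> O with constant rates k1 (open) and k2 (close)."""
    params = [Parameter("k1"), Parameter("k2"), Parameter("g", "conductance")]
    if extra_param:
        params.insert(2, Parameter("k3"))
    return KineticModel(
        name="toy-two-state",
        states=("C", "O"),
        transitions=(Transition("C", "O", "k1"), Transition("O", "C", "k2")),
        parameters=tuple(params),
        conductance_param="g",
        open_state="O",
        reversal_potential=-93.0,
    )


class TestStates:
    def test_constant_voltage_stays_at_steady_state(self, wang_r0, theta0):
        p = VoltageProtocol(((500.0, -40.0, -40.0),))
        ss = steady_state(wang_r0, -40.0, theta0)
        times, X = simulate_states(wang_r0, p, theta0, times=np.linspace(0, 500, 21))
        assert np.allclose(X, ss[None, :], atol=1e-8)

    def test_two_state_monoexponential_relaxation(self):
        """Closed form: O(t) = O_inf + (O_0 - O_inf) exp(-(k1+k2) t) after a
        rate switch, realised here by a voltage-independent model started
        from a non-equilibrium initial state via a preceding segment."""
        m = two_state_model()
        theta = ParameterVector({"k1": 0.05, "k2": 0.02, "g": 1.0})
        p = VoltageProtocol(((200.0, -80.0, -80.0),))
        # voltage-independent rates: steady state everywhere = k1/(k1+k2)
        times, X = simulate_states(m, p, theta, times=np.linspace(0, 200, 11))
        assert np.allclose(X[:, 1], 0.05 / 0.07, atol=1e-9)
        # analytic relaxation from O(0)=0 oracle vs a manual ODE solve
        from scipy.integrate import solve_ivp

        k1, k2 = 0.05, 0.02
        sol = solve_ivp(
            lambda t, y: [k1 * (1 - y[0]) - k2 * y[0]], (0, 100), [0.0], rtol=1e-10,
            atol=1e-12, t_eval=[100.0],
        )
        analytic = k1 / (k1 + k2) * (1 - np.exp(-(k1 + k2) * 100.0))
        assert sol.y[0, -1] == pytest.approx(analytic, abs=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=10)
    def test_conservation_across_models(self, wang_sequence, protocol, seed):
        rng = np.random.default_rng(seed)
        model = wang_sequence[seed % len(wang_sequence)][0]
        vals = {}
        for p in model.parameters:
            if p.kind == "slope":
                vals[p.name] = 10 ** rng.uniform(-4, np.log10(0.25))
            else:
                vals[p.name] = 10 ** rng.uniform(-3, 2)
        times, X = simulate_states(
            model, protocol, ParameterVector(vals), times=np.linspace(0, 5000, 26)
        )
        assert np.abs(X.sum(axis=1) - 1.0).max() < 1e-6
        assert X.min() > -1e-6 and X.max() < 1 + 1e-6


class TestCurrent:
    def test_zero_driving_force_zero_current(self, wang_r0, theta0):
        e = wang_r0.reversal_potential
        p = VoltageProtocol(((1000.0, e, e),))
        tr = simulate_current(wang_r0, p, theta0, uniform_schedule(p, 20))
        assert np.abs(tr.currents).max() == 0.0

    def test_linearity_in_conductance(self, wang_r0, theta0, protocol):
        s = uniform_schedule(protocol, 50)
        tr1 = simulate_current(wang_r0, protocol, theta0, s)
        doubled = dict(theta0.values)
        doubled["g"] *= 2
        tr2 = simulate_current(wang_r0, protocol, ParameterVector(doubled), s)
        assert np.allclose(tr2.currents, 2 * tr1.currents, rtol=1e-9, atol=1e-12)

    def test_steady_state_current_matches_nullspace_oracle(self, wang_r0, theta0):
        v = 0.0
        p = VoltageProtocol(((20000.0, v, v),))
        tr = simulate_current(wang_r0, p, theta0, MeasurementSchedule((20000.0,)))
        ss = steady_state(wang_r0, v, theta0)
        o = ss[wang_r0.states.index("O")]
        expected = theta0["g"] * o * (v - wang_r0.reversal_potential)
        assert tr.currents[-1] == pytest.approx(expected, rel=1e-5)

    def test_exact_propagator_matches_ode_solver(self, wang_r0, theta0, protocol):
        s = uniform_schedule(protocol, 200)
        a = simulate_current(wang_r0, protocol, theta0, s)
        b = simulate_current(wang_r0, protocol, theta0, s, ODE_SOLVER)
        assert np.abs(a.currents - b.currents).max() < 1e-5

    def test_overflowing_parameters_raise_recoverable_error(self, wang_r0, theta0, protocol):
        crazy = dict(theta0.values)
        crazy["p12"] = 50.0  # exp(50*60) overflows
        with pytest.raises(SimulationError):
            simulate_current(
                wang_r0, protocol, ParameterVector(crazy), uniform_schedule(protocol, 10)
            )


class TestSensitivities:
    def test_conductance_column_equals_output(self, wang_r0, theta0, protocol, schedule37):
        st_ = simulate_sensitivities(wang_r0, protocol, theta0, schedule37)
        gcol = st_.jacobian[:, list(st_.parameter_names).index("g")]
        assert np.allclose(gcol, st_.outputs, rtol=1e-6, atol=1e-9)

    def test_unreferenced_parameter_has_zero_column(self, protocol):
        m = two_state_model(extra_param=True)
        theta = ParameterVector({"k1": 0.05, "k2": 0.02, "k3": 1.0, "g": 0.5})
        st_ = simulate_sensitivities(m, protocol, theta, uniform_schedule(protocol, 25))
        k3 = st_.jacobian[:, list(st_.parameter_names).index("k3")]
        assert np.abs(k3).max() == 0.0

    def test_jacobian_matches_central_differences(self, wang_r0, theta0, protocol, schedule37):
        """>= 20 spot checks of dy/dlog(theta) against two-sided finite
        differences with relative step 1e-4, mixed tolerance 1e-3."""
        st_ = simulate_sensitivities(wang_r0, protocol, theta0, schedule37)
        h = 1e-4
        rng = np.random.default_rng(0)
        names = list(st_.parameter_names)
        checked = 0
        for name in ("p1", "p2", "p4", "p7", "p10", "p12", "g"):
            up, dn = dict(theta0.values), dict(theta0.values)
            up[name] *= np.exp(h)
            dn[name] *= np.exp(-h)
            yu = simulate_current(wang_r0, protocol, ParameterVector(up), schedule37).currents
            yd = simulate_current(wang_r0, protocol, ParameterVector(dn), schedule37).currents
            fd = (yu - yd) / (2 * h)
            col = st_.jacobian[:, names.index(name)]
            for idx in rng.choice(len(fd), size=3, replace=False):
                checked += 1
                err = abs(fd[idx] - col[idx]) / (1 + abs(fd[idx]))
                assert err < 1e-3, (name, idx, err)
        assert checked >= 20


class TestTraceIO:
    def test_round_trip(self, tmp_path):
        tr = CurrentTrace(np.array([1.0, 2.0, 3.0]), np.array([0.1, -0.2, 0.5]))
        f = tmp_path / "t.csv"
        write_trace_csv(tr, f)
        back = read_trace_csv(f)
        assert np.allclose(back.times, tr.times)
        assert np.allclose(back.currents, tr.currents)

    def test_bad_columns(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="time_ms"):
            read_trace_csv(f)

    def test_trace_invariants(self):
        with pytest.raises(ValueError):
            CurrentTrace(np.array([1.0, 1.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            CurrentTrace(np.array([1.0, 2.0]), np.array([np.nan, 0.0]))
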