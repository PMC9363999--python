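"""Symbolic limit application and the shipped Wang reduction sequence."""

import numpy as np
import pytest
import sympy as sp

from mbamkit import (
    KineticModel,
    LimitSpec,
    NewParameter,
    Parameter,
    ParameterVector,
    UnsupportedLimitError,
    apply_limit,
    derive_wang_sequence,
    fixture_theta,
    limit_consistency_check,
    rate_matrix,
    uniform_schedule,
    wang_limit_specs,
    wang_reduction_sequence,
)
from mbamkit.models import Transition


class TestWangSequenceStructure:
    def test_nine_models_with_strictly_decreasing_parameters(self, wang_sequence):
        assert len(wang_sequence) == 9
        counts = [len(m.parameters) for m, _ in wang_sequence]
        assert counts == list(range(15, 6, -1))

    def test_state_counts_non_increasing_five_to_two(self, wang_sequence):
        states = [len(m.states) for m, _ in wang_sequence]
        assert states[0] == 5
        assert states[-1] == 2
        assert all(a >= b for a, b in zip(states, states[1:]))

    def test_limit_taxonomy_four_four_one(self):
        kinds = [s.kind for s in wang_limit_specs()]
        assert kinds.count("zero") == 4
        assert kinds.count("ratio") == 4
        assert kinds.count("product") == 1

    def test_rederivation_equals_frozen_fixtures(self, wang_sequence):
        derived, _ = derive_wang_sequence()
        for (frozen, _), model in zip(wang_sequence, derived):
            assert frozen == model

    @staticmethod
    def _printed(expr, state):
        local = {
            state: sp.Symbol(state, nonnegative=True),
            "V": sp.Symbol("V", real=True),
        }
        for p in ("phi3", "phi7", "p4", "p8"):
            local[p] = sp.Symbol(p, positive=True)
        return sp.sympify(expr, locals=local)

    def test_r5_carries_printed_open_state_correction(self, wang_models):
        r5 = wang_models["wang-r5"]
        printed = self._printed("Op/(1 + phi3*exp(-p4*V))", "Op")
        assert sp.simplify(r5.observable_symbolic() - printed) == 0

    def test_r8_is_two_state_with_instantaneous_inactivation(self, wang_models):
        r8 = wang_models["wang-r8"]
        assert len(r8.states) == 2
        assert len(r8.parameters) == 7
        printed = self._printed("Opp/(1 + phi7*exp(p8*V))", "Opp")
        assert sp.simplify(r8.observable_symbolic() - printed) == 0

    def test_reduced_models_conserve_probability(self, wang_sequence, rng):
        for model, _ in wang_sequence:
            vals = {
                p.name: (10 ** rng.uniform(-2, 1) if p.kind != "slope" else 0.02)
                for p in model.parameters
            }
            q = rate_matrix(model, -20.0, ParameterVector(vals))
            assert np.abs(q.sum(axis=0)).max() < 1e-12 * max(1.0, np.abs(q).max())


class TestApplyLimit:
    def test_slope_to_zero_makes_rate_constant(self, wang_models):
        r3 = wang_models["wang-r3"]
        spec = [s for s in wang_limit_specs() if s.zeros == ("p2",)][0]
        r4 = apply_limit(r3, spec)
        assert len(r4.parameters) == len(r3.parameters) - 1
        assert len(r4.states) == len(r3.states)
        rate = [t.rate for t in r4.transitions if (t.source, t.target) == ("C23", "O")][0]
        assert sp.sympify(rate, locals={"p1": sp.Symbol("p1")}) == sp.Symbol("p1")

    def test_prefactor_to_zero_deletes_transition(self):
        m = KineticModel(
            name="chain",
            states=("A", "B", "C"),
            transitions=(
                Transition("A", "B", "k1"),
                Transition("B", "A", "k2"),
                Transition("B", "C", "k3"),
                Transition("C", "B", "k4"),
            ),
            parameters=tuple(
                [Parameter(k) for k in ("k1", "k2", "k3", "k4")]
                + [Parameter("g", "conductance")]
            ),
            conductance_param="g",
            open_state="C",
        )
        red = apply_limit(m, LimitSpec(label="k4 -> 0", zeros=("k4",)))
        assert len(red.transitions) == 3
        assert "k4" not in red.parameter_names

    def test_lumping_introduces_observable_correction(self, wang_models):
        r7 = wang_models["wang-r7"]
        spec = [s for s in wang_limit_specs() if s.result_name == "wang-r8"][0]
        r8 = apply_limit(r7, spec)
        assert r8.open_state == "Opp"
        assert "phi7" in r8.observable

    def test_conductance_limit_requires_manual_reduction(self, wang_models):
        r8 = wang_models["wang-r8"]
        spec = LimitSpec(
            label="g -> inf",
            infinities=("g", "p11"),
            new_parameters=(NewParameter("phi9", "ratio", numerator="g", denominator="p11"),),
        )
        with pytest.raises(UnsupportedLimitError, match="manual"):
            apply_limit(r8, spec)

    def test_diverging_parameter_without_combination_fails_loudly(self, wang_models):
        r6 = wang_models["wang-r6"]
        with pytest.raises(UnsupportedLimitError):
            apply_limit(r6, LimitSpec(label="p7 -> inf alone", infinities=("p7",)))

    def test_spec_referencing_absent_parameter(self, wang_models):
        with pytest.raises(Exception, match="p5"):
            apply_limit(wang_models["wang-r3"], LimitSpec(label="bad", zeros=("p5",)))


class TestConsistency:
    def test_identity_spec_gives_zero_error(self, wang_models, protocol):
        r6 = wang_models["wang-r6"]
        sched = uniform_schedule(protocol, 5000)
        rep = limit_consistency_check(
            r6, r6, LimitSpec(label="identity"), protocol, sched, fixture_theta("wang-r6")
        )
        assert rep["passed"]
        assert all(r["emrms"] < 1e-12 for r in rep["rows"])

    def test_two_state_lumping_toy_converges(self, protocol):
        """A three-state chain whose last pair equilibrates instantly: the
        lumped two-state model is the quasi-steady-state limit, so the
        mismatch must shrink as the fast rates grow."""
        toy = KineticModel(
            name="toy3",
            states=("C", "O", "B"),
            transitions=(
                Transition("C", "O", "a1*exp(b1*V)"),
                Transition("O", "C", "a2*exp(-b2*V)"),
                Transition("O", "B", "kf"),
                Transition("B", "O", "kb"),
            ),
            parameters=tuple(
                [Parameter("a1"), Parameter("b1", "slope"), Parameter("a2"),
                 Parameter("b2", "slope"), Parameter("kf"), Parameter("kb"),
                 Parameter("g", "conductance")]
            ),
            conductance_param="g",
            open_state="O",
        )
        spec = LimitSpec(
            label="kf,kb -> inf",
            infinities=("kf", "kb"),
            new_parameters=(NewParameter("phi", "ratio", numerator="kf", denominator="kb"),),
        )
        red = apply_limit(toy, spec)
        assert len(red.states) == 2
        theta = ParameterVector(
            {"a1": 0.05, "b1": 0.03, "a2": 0.02, "b2": 0.04, "kf": 2.0, "kb": 1.0, "g": 0.2}
        )
        sched = uniform_schedule(protocol, 5000)
        rep = limit_consistency_check(toy, red, spec, protocol, sched, theta)
        errs = [r["emrms"] for r in rep["rows"]]
        assert rep["passed"]
        assert errs[0] > errs[-1]

    def test_wang_r4_to_r5_converges_under_documented_limit(self, wang_sequence, protocol):
        r4, spec = wang_sequence[4]
        r5 = wang_sequence[5][0]
        sched = uniform_schedule(protocol, 5000)
        rep = limit_consistency_check(
            r4, r5, spec, protocol, sched, fixture_theta("wang-r4")
        )
        assert rep["passed"], rep
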