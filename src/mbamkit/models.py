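"""Markov-chain ion channel models as symbolic kinetic schemes.

A :class:`KineticModel` is a continuous-time Markov chain over channel
conformations (closed/open/inactivated states) with voltage-dependent
transition rates, an observable open probability and a conductance, so that
the macroscopic current is ``I = g * O * (V - E_rev)``.

Hand-built models use rates of the exponential family ``A*exp(s*B*V)``
(:class:`RateExpression`); models produced by boundary-limit reduction may
carry more general symbolic rates (for example logistic "gate" factors that
arise when a fast-equilibrating state pair is lumped), which is why
transitions store sympy expressions rather than (A, B) pairs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp
from scipy.linalg import null_space

__all__ = [
    "RateExpression",
    "Parameter",
    "KineticModel",
    "ParameterVector",
    "ModelError",
    "SchemaError",
    "build_wang_r0",
    "rate_matrix",
    "steady_state",
    "nernst_potential",
    "serialize_model",
    "parse_model",
]

# Gas constant / Faraday, in mV units: R*T/F = RT_F_MV * T [K]
_RT_OVER_F_PER_K = 1000.0 * 8.314462618 / 96485.33212  # mV per kelvin

#: Default reversal potential: Nernst potential for K+ with 4 mM external /
#: 130 mM internal at 37 C (310.15 K), matching typical bath/pipette
#: solutions for hERG recordings in HEK cells.
DEFAULT_E_REV = None  # filled in below, after nernst_potential is defined


class ModelError(ValueError):
    """Invalid model construction or evaluation."""


class SchemaError(ModelError):
    """Model document violates the JSON schema; message carries a path."""


def _symbols(names):
    return {n: sp.Symbol(n, positive=True) for n in names}


def _parse(expr: str, local: dict):
    """Parse an expression string with an explicit symbol table.

    Bare ``sympify`` would interpret ``I``, ``O`` and ``E`` as the imaginary
    unit, big-O order and Euler's number; state names like C1/O/I are common
    in gating schemes, so every known name is bound explicitly.
    """
    try:
        e = sp.parse_expr(expr, local_dict=local, evaluate=True)
    except Exception as exc:  # pragma: no cover - sympy error text varies
        raise SchemaError(f"cannot parse expression {expr!r}: {exc}") from exc
    return e


@dataclass(frozen=True)
class RateExpression:
    """A transition rate of the form ``A * exp(sign * B * V)``.

    Parameters
    ----------
    prefactor_param:
        Name of the prefactor parameter A (ms^-1, strictly positive).
    voltage_slope_param:
        Name of the voltage-slope parameter B (mV^-1), or ``None`` for a
        voltage-independent rate.
    sign:
        +1 or -1 multiplying V in the exponent.
    """

    prefactor_param: str
    voltage_slope_param: str | None = None
    sign: int = 1

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ModelError(f"sign must be +1 or -1, got {self.sign}")

    def to_string(self) -> str:
        if self.voltage_slope_param is None:
            return self.prefactor_param
        s = "" if self.sign > 0 else "-"
        return f"{self.prefactor_param}*exp({s}{self.voltage_slope_param}*V)"


@dataclass(frozen=True)
class Parameter:
    """A named model parameter with its optimisation class.

    kind is one of ``prefactor`` (A-type, ms^-1), ``slope`` (B-type, mV^-1),
    ``conductance`` (uS) or ``combined`` (a dimensionful ratio/product formed
    at a manifold boundary). Prefactor, conductance and combined parameters
    are log-transformed during fitting; slope parameters stay linear.
    """

    name: str
    kind: str = "prefactor"

    _KINDS = ("prefactor", "slope", "conductance", "combined")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ModelError(f"unknown parameter kind {self.kind!r}")

    @property
    def log_transformed(self) -> bool:
        return self.kind != "slope"


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    rate: str  # sympy-parseable expression in V and parameter names


@dataclass
class ParameterVector:
    """Parameter values keyed by name, in linear or natural-log space."""

    values: dict
    space: str = "linear"  # "linear" | "log"

    def __post_init__(self):
        if self.space not in ("linear", "log"):
            raise ModelError(f"space must be 'linear' or 'log', got {self.space!r}")
        if self.space == "linear":
            bad = [k for k, v in self.values.items() if not (v > 0)]
            if bad:
                raise ModelError(f"non-positive linear-space values for {bad}")

    def to_log(self) -> "ParameterVector":
        if self.space == "log":
            return self
        return ParameterVector({k: math.log(v) for k, v in self.values.items()}, "log")

    def to_linear(self) -> "ParameterVector":
        if self.space == "linear":
            return self
        return ParameterVector({k: math.exp(v) for k, v in self.values.items()}, "linear")

    def array(self, names) -> np.ndarray:
        try:
            return np.array([self.values[n] for n in names], dtype=float)
        except KeyError as exc:
            raise ModelError(f"missing parameter {exc.args[0]!r}") from exc

    def __getitem__(self, name):
        return self.values[name]


@dataclass(frozen=True)
class KineticModel:
    """A voltage-dependent Markov gating scheme with an observable current.

    Attributes
    ----------
    name:
        Identifier, e.g. ``"wang-r0"``.
    states:
        Ordered state names. The first state is the one eliminated through
        probability conservation when simulating (x1 = 1 - sum of the rest).
    transitions:
        Directed transitions with symbolic rate expressions.
    parameters:
        Ordered :class:`Parameter` declarations, including the conductance.
    conductance_param:
        Name of the maximal-conductance parameter (uS).
    open_state:
        Name of the (surrogate) open state the observable is built from.
    observable:
        Symbolic expression for the open probability in terms of state
        names, parameters and V. Defaults to the open state itself; reduced
        models may carry corrections such as ``Op/(1 + phi3*exp(-p4*V))``.
    reversal_potential:
        E_rev in mV (driving force is V - E_rev).
    """

    name: str
    states: tuple
    transitions: tuple
    parameters: tuple
    conductance_param: str
    open_state: str
    observable: str | None = None
    reversal_potential: float = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.reversal_potential is None:
            object.__setattr__(self, "reversal_potential", DEFAULT_E_REV)
        if self.observable is None:
            object.__setattr__(self, "observable", self.open_state)
        self._validate()

    # -- structure ---------------------------------------------------------

    @property
    def parameter_names(self) -> tuple:
        return tuple(p.name for p in self.parameters)

    @property
    def kinetic_parameter_names(self) -> tuple:
        return tuple(p.name for p in self.parameters if p.kind != "conductance")

    def parameter(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise ModelError(f"unknown parameter {name!r} in model {self.name!r}")

    def _symbol_table(self):
        local = _symbols(self.parameter_names)
        local.update({s: sp.Symbol(s, nonnegative=True) for s in self.states})
        local["V"] = sp.Symbol("V", real=True)
        return local

    def _validate(self):
        if len(set(self.states)) != len(self.states) or not self.states:
            raise SchemaError("states: must be a non-empty list of unique names")
        if len(set(self.parameter_names)) != len(self.parameters):
            raise SchemaError("parameters: duplicate names")
        if self.open_state not in self.states:
            raise SchemaError(f"open_state: unknown state {self.open_state!r}")
        if self.conductance_param not in self.parameter_names:
            raise SchemaError(
                f"conductance: parameter {self.conductance_param!r} not declared"
            )
        local = self._symbol_table()
        psyms = {local[p] for p in self.parameter_names}
        vsym = local["V"]
        for i, t in enumerate(self.transitions):
            for end in (t.source, t.target):
                if end not in self.states:
                    raise SchemaError(f"transitions[{i}]: unknown state {end!r}")
            if t.source == t.target:
                raise SchemaError(f"transitions[{i}]: self-loop on {t.source!r}")
            expr = _parse(t.rate, local)
            extra = expr.free_symbols - psyms - {vsym}
            if extra:
                names = sorted(s.name for s in extra)
                raise SchemaError(
                    f"transitions[{i}].rate: undeclared symbol(s) {names}"
                )
        obs = _parse(self.observable, local)
        ssyms = {local[s] for s in self.states}
        extra = obs.free_symbols - psyms - ssyms - {vsym}
        if extra:
            raise SchemaError(
                f"observable: undeclared symbol(s) {sorted(s.name for s in extra)}"
            )
        # connectivity of the undirected transition graph
        adj = {s: set() for s in self.states}
        for t in self.transitions:
            adj[t.source].add(t.target)
            adj[t.target].add(t.source)
        seen, stack = set(), [self.states[0]]
        while stack:
            s = stack.pop()
            if s in seen:
                continue
            seen.add(s)
            stack.extend(adj[s] - seen)
        if seen != set(self.states):
            raise SchemaError(
                f"transition graph is disconnected; unreachable: {sorted(set(self.states) - seen)}"
            )

    # -- symbolic views ----------------------------------------------------

    def rate_matrix_symbolic(self) -> sp.Matrix:
        """N x N generator matrix Q with zero column sums.

        Entry ``Q[i, j]`` (i != j) is the rate of the j -> i transition;
        the diagonal holds minus the column's off-diagonal sum, so that
        ``dX/dt = Q X`` conserves total probability.
        """
        local = self._symbol_table()
        idx = {s: k for k, s in enumerate(self.states)}
        n = len(self.states)
        Q = sp.zeros(n, n)
        for t in self.transitions:
            r = _parse(t.rate, local)
            Q[idx[t.target], idx[t.source]] += r
            Q[idx[t.source], idx[t.source]] -= r
        return Q

    def observable_symbolic(self) -> sp.Expr:
        return _parse(self.observable, self._symbol_table())

    def with_name(self, name: str) -> "KineticModel":
        return replace(self, name=name)

    def __eq__(self, other):
        if not isinstance(other, KineticModel):
            return NotImplemented
        return (
            self.name == other.name
            and self.states == other.states
            and self.transitions == other.transitions
            and self.parameters == other.parameters
            and self.conductance_param == other.conductance_param
            and self.open_state == other.open_state
            and sp.simplify(self.observable_symbolic() - other.observable_symbolic()) == 0
            and abs(self.reversal_potential - other.reversal_potential) < 1e-12
        )

    __hash__ = None  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# numerical operations


def nernst_potential(k_out: float, k_in: float, temperature: float = 310.15) -> float:
    """Nernst reversal potential (mV) for a monovalent cation.

    Parameters are the external and internal concentrations (mM, any common
    unit as only the ratio matters) and the absolute temperature (K).
    """
    if not (k_out > 0 and k_in > 0 and temperature > 0):
        raise ModelError("concentrations and temperature must be positive")
    return _RT_OVER_F_PER_K * temperature * math.log(k_out / k_in)


DEFAULT_E_REV = nernst_potential(4.0, 130.0, 310.15)


def rate_matrix(model: KineticModel, v: float, theta: ParameterVector) -> np.ndarray:
    """Numeric generator matrix Q(V, theta) over ``model.states``."""
    from .simulate import compile_model  # local import to avoid a cycle

    theta = theta.to_linear()
    cm = compile_model(model)
    return cm.rate_matrix(v, theta.array(model.parameter_names))


def steady_state(model: KineticModel, v: float, theta: ParameterVector) -> np.ndarray:
    """Stationary occupancy distribution at a fixed voltage.

    Returns the unique probability vector in the null space of Q(V). Raises
    :class:`ModelError` if the null space is not one-dimensional (reducible
    or defective scheme) or the distribution is not non-negative.
    """
    q = rate_matrix(model, v, theta)
    ns = null_space(q, rcond=1e-10)
    if ns.shape[1] != 1:
        raise ModelError(
            f"rate matrix at V={v} has a {ns.shape[1]}-dimensional null space; "
            "steady state is not unique"
        )
    x = ns[:, 0]
    x = x / x.sum()
    if np.any(x < -1e-9):
        raise ModelError(f"steady state has negative entries at V={v}: {x}")
    return np.clip(x, 0.0, None) / np.clip(x, 0.0, None).sum()


# ---------------------------------------------------------------------------
# the Wang five-state hERG scheme


def build_wang_r0() -> KineticModel:
    """The five-state Wang model of hERG channel gating (revision r0).

    Three closed states, one open and one inactivated state arranged as
    ``C1 <-> C2 <-> C3 <-> O <-> I``, with 14 kinetic parameters and one
    maximal conductance:

    ========  =====================  ==================
    rate      transition             expression
    ========  =====================  ==================
    alpha_a0  C1 -> C2               p11*exp(p12*V)
    beta_a0   C2 -> C1               p13*exp(-p14*V)
    k_f       C2 -> C3               p5
    k_b       C3 -> C2               p6
    alpha_a1  C3 -> O                p1*exp(p2*V)
    beta_a1   O -> C3                p3*exp(-p4*V)
    alpha_1   O -> I                 p7*exp(p8*V)
    beta_1    I -> O                 p9*exp(-p10*V)
    ========  =====================  ==================

    The observable current is ``I_Kr = g_Kr * O * (V - E_Kr)``.
    """
    rates = [
        ("C1", "C2", RateExpression("p11", "p12", +1)),
        ("C2", "C1", RateExpression("p13", "p14", -1)),
        ("C2", "C3", RateExpression("p5")),
        ("C3", "C2", RateExpression("p6")),
        ("C3", "O", RateExpression("p1", "p2", +1)),
        ("O", "C3", RateExpression("p3", "p4", -1)),
        ("O", "I", RateExpression("p7", "p8", +1)),
        ("I", "O", RateExpression("p9", "p10", -1)),
    ]
    transitions = tuple(Transition(a, b, r.to_string()) for a, b, r in rates)
    params = []
    for i in range(1, 15):
        kind = "slope" if i in (2, 4, 8, 10, 12, 14) else "prefactor"
        params.append(Parameter(f"p{i}", kind))
    params.append(Parameter("g", "conductance"))
    return KineticModel(
        name="wang-r0",
        states=("C1", "C2", "C3", "O", "I"),
        transitions=transitions,
        parameters=tuple(params),
        conductance_param="g",
        open_state="O",
    )


# ---------------------------------------------------------------------------
# serialization

_SCHEMA = "mbamkit-model/1"


def serialize_model(model: KineticModel) -> str:
    doc = {
        "schema": _SCHEMA,
        "name": model.name,
        "states": list(model.states),
        "open_state": model.open_state,
        "observable": model.observable,
        "conductance": model.conductance_param,
        "reversal_potential_mV": model.reversal_potential,
        "parameters": [{"name": p.name, "kind": p.kind} for p in model.parameters],
        "transitions": [
            {"from": t.source, "to": t.target, "rate": t.rate} for t in model.transitions
        ],
        "units": {"time": "ms", "voltage": "mV", "conductance": "uS", "current": "nA"},
        "meta": model.meta,
    }
    return json.dumps(doc, indent=1)


def _require(doc, key, typ, path):
    if key not in doc:
        raise SchemaError(f"{path}: missing required field {key!r}")
    if typ is not None and not isinstance(doc[key], typ):
        raise SchemaError(f"{path}.{key}: expected {typ.__name__}")
    return doc[key]


def parse_model(text: str) -> KineticModel:
    """Parse a model JSON document, reporting schema violations with a path."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"$: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise SchemaError("$: document must be a JSON object")
    if doc.get("schema") != _SCHEMA:
        raise SchemaError(f"$.schema: expected {_SCHEMA!r}, got {doc.get('schema')!r}")
    states = tuple(_require(doc, "states", list, "$"))
    params = []
    for i, p in enumerate(_require(doc, "parameters", list, "$")):
        params.append(
            Parameter(
                _require(p, "name", str, f"$.parameters[{i}]"),
                p.get("kind", "prefactor"),
            )
        )
    transitions = []
    for i, t in enumerate(_require(doc, "transitions", list, "$")):
        transitions.append(
            Transition(
                _require(t, "from", str, f"$.transitions[{i}]"),
                _require(t, "to", str, f"$.transitions[{i}]"),
                _require(t, "rate", str, f"$.transitions[{i}]"),
            )
        )
    return KineticModel(
        name=_require(doc, "name", str, "$"),
        states=states,
        transitions=tuple(transitions),
        parameters=tuple(params),
        conductance_param=_require(doc, "conductance", str, "$"),
        open_state=_require(doc, "open_state", str, "$"),
        observable=doc.get("observable"),
        reversal_potential=doc.get("reversal_potential_mV"),
        meta=doc.get("meta", {}),
    )
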