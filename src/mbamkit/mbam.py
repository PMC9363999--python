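"""Manifold-boundary engine: sensitivity metric, geodesics, limit finding.

The model manifold is the image of parameter space under the map
``theta -> (y_1, ..., y_M)`` of outputs at the measurement schedule. Working
in natural-log parameters ``rho = log(theta)``, the pull-back metric is the
Gauss-Newton/Fisher matrix ``g = J^T J`` with ``J_mi = dy_m/drho_i``. From a
calibrated point the geodesic equation

    d2rho/dtau2 = -g^{-1} J^T A(v),    A_m(v) = v^T (d2y_m/drho2) v

is integrated along the sloppiest eigenvector of g until the smallest
eigenvalue collapses, which signals a boundary of the manifold: a limit in
which parameters go to 0 or infinity, possibly in finite combinations. The
second directional derivative is estimated with a central finite difference,
``A_m = (y(rho + h v) - 2 y(rho) + y(rho - h v)) / h^2``.

The engine only needs an output map and its Jacobian, so it works both for
kinetic channel models (:class:`KineticOutput`) and for analytic toy models
used in testing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import RK45

from .models import KineticModel, ParameterVector
from .protocols import MeasurementSchedule, VoltageProtocol
from .simulate import (
    FAST_SOLVER,
    SimulationError,
    SolverOptions,
    simulate_current,
    simulate_sensitivities,
)

__all__ = [
    "MetricResult",
    "GeodesicOptions",
    "GeodesicPath",
    "LimitClassification",
    "KineticOutput",
    "metric",
    "directional_second_derivative",
    "geodesic_rhs",
    "integrate_geodesic",
    "classify_limit",
]


# ---------------------------------------------------------------------------
# output-map interface


class KineticOutput:
    """Output map of a kinetic model under a protocol/schedule.

    Exposes ``outputs(rho)`` and ``jacobian(rho)`` in log-parameter space,
    with a small cache so that the eigenvalue monitoring of the geodesic
    integrator reuses the Jacobian computed for the right-hand side.
    """

    def __init__(
        self,
        model: KineticModel,
        protocol: VoltageProtocol,
        schedule: MeasurementSchedule,
        solver_opts: SolverOptions | None = None,
    ):
        self.model = model
        self.protocol = protocol
        self.schedule = schedule
        self.solver_opts = solver_opts or FAST_SOLVER
        self.parameter_names = model.parameter_names
        self._jcache: dict = {}

    def _theta(self, rho: np.ndarray) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        if np.any(np.abs(rho) > 700):
            raise SimulationError("log-parameters out of floating-point range")
        return np.exp(rho)

    def outputs(self, rho: np.ndarray) -> np.ndarray:
        tr = simulate_current(
            self.model, self.protocol, self._theta(rho), self.schedule, self.solver_opts
        )
        return tr.currents

    def jacobian(self, rho: np.ndarray):
        key = np.asarray(rho, dtype=float).tobytes()
        hit = self._jcache.get(key)
        if hit is not None:
            return hit
        st = simulate_sensitivities(
            self.model, self.protocol, self._theta(rho), self.schedule, self.solver_opts
        )
        res = (st.outputs, st.jacobian)
        if len(self._jcache) > 64:
            self._jcache.clear()
        self._jcache[key] = res
        return res


# ---------------------------------------------------------------------------
# metric


@dataclass(frozen=True)
class MetricResult:
    """Eigen-analysis of the sensitivity metric g = J^T J."""

    matrix: np.ndarray
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns matching eigenvalues
    parameter_names: tuple = ()

    @property
    def lambda_max(self) -> float:
        return float(self.eigenvalues[0])

    @property
    def lambda_min(self) -> float:
        return float(self.eigenvalues[-1])

    @property
    def condition_ratio(self) -> float:
        """lambda_min / lambda_max; << 1 for sloppy models."""
        return self.lambda_min / self.lambda_max

    @property
    def sloppiest_direction(self) -> np.ndarray:
        """Unit eigenvector of the smallest eigenvalue, sign-normalised so
        its largest-magnitude component is positive."""
        v = self.eigenvectors[:, -1].copy()
        k = int(np.argmax(np.abs(v)))
        if v[k] < 0:
            v = -v
        return v


def metric(jacobian: np.ndarray, parameter_names=()) -> MetricResult:
    """Build g = J^T J and its full eigendecomposition.

    Eigenvalues are returned in descending order. A warning is raised when
    there are fewer measurements than parameters (rank-deficient metric).
    """
    J = np.asarray(jacobian, dtype=float)
    if not np.all(np.isfinite(J)):
        raise ValueError("jacobian contains non-finite entries")
    m, n = J.shape
    if m < n:
        warnings.warn(
            f"metric built from {m} measurements for {n} parameters is rank-deficient",
            stacklevel=2,
        )
    g = J.T @ J
    g = 0.5 * (g + g.T)
    w, V = np.linalg.eigh(g)
    order = np.argsort(w)[::-1]
    return MetricResult(g, w[order], V[:, order], tuple(parameter_names))


# ---------------------------------------------------------------------------
# geodesic pieces


def directional_second_derivative(outputs, rho, v, h, y0=None):
    """Central second difference of the output map along direction v.

    ``outputs`` maps log-parameters to the output vector; evaluation
    failures at the displaced points propagate as :class:`SimulationError`
    so callers may shrink h and retry.
    """
    if not h > 0:
        raise ValueError("h must be positive")
    rho = np.asarray(rho, dtype=float)
    v = np.asarray(v, dtype=float)
    if y0 is None:
        y0 = outputs(rho)
    yp = outputs(rho + h * v)
    ym = outputs(rho - h * v)
    return (yp - 2.0 * y0 + ym) / h**2


def geodesic_rhs(J: np.ndarray, A: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
    """Acceleration -g^{-1} J^T A, with a pseudo-inverse cutoff for
    near-singular metrics (the situation at a boundary)."""
    g = J.T @ J
    g = 0.5 * (g + g.T)
    rhs = J.T @ np.asarray(A, dtype=float)
    w, V = np.linalg.eigh(g)
    cut = rcond * np.max(np.abs(w)) if w.size else 0.0
    inv = np.where(np.abs(w) > cut, 1.0 / np.where(w == 0, 1.0, w), 0.0)
    return -(V @ (inv * (V.T @ rhs)))


@dataclass(frozen=True)
class GeodesicOptions:
    """Knobs for geodesic integration.

    eig_threshold:
        Boundary stopping criterion on the smallest metric eigenvalue
        (default 1e-6; occasionally needs tuning per starting model).
    tau_max:
        Affine-parameter budget.
    log_cap:
        Stop when any |log theta_i| exceeds this (parameters effectively at
        0 or infinity; guards against overflow).
    h:
        Finite-difference step for the directional second derivative, in
        log-parameter space; a single Richardson halving check at the start
        shrinks it if the estimate looks unconverged.
    renormalize_velocity:
        Optional arc-length-style rescaling of v to unit norm after each
        step (off by default; the raw second-order system is integrated).
    """

    eig_threshold: float = 1e-6
    tau_max: float = 1000.0
    log_cap: float = 25.0
    h: float = 1e-2
    rtol: float = 1e-6
    atol: float = 1e-9
    max_steps: int = 4000
    initial_step: float = 1e-3
    retry_opposite_sign: bool = True
    renormalize_velocity: bool = False
    rcond: float = 1e-12


@dataclass
class GeodesicPath:
    """A geodesic through log-parameter space with its metric diagnostics."""

    taus: np.ndarray
    log_params: np.ndarray  # (K, N)
    velocities: np.ndarray  # (K, N)
    lambda_min: np.ndarray  # (K,)
    parameter_names: tuple
    termination: str  # boundary | log_cap | tau_max | solver_failure | no_progress
    meta: dict = field(default_factory=dict)

    @property
    def terminal_velocity(self) -> np.ndarray:
        """Unit velocity at the end of the path."""
        v = self.velocities[-1]
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("terminal velocity is zero")
        return v / n

    @property
    def terminal_log_params(self) -> np.ndarray:
        return self.log_params[-1]

    def to_frame(self):
        import pandas as pd

        cols = {"tau": self.taus, "lambda_min": self.lambda_min}
        for i, n in enumerate(self.parameter_names):
            cols[f"log_{n}"] = self.log_params[:, i]
        for i, n in enumerate(self.parameter_names):
            cols[f"v_{n}"] = self.velocities[:, i]
        return pd.DataFrame(cols)

    def write_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "termination": self.termination,
            "n_points": int(len(self.taus)),
            "tau_end": float(self.taus[-1]),
            "lambda_min_start": float(self.lambda_min[0]),
            "lambda_min_end": float(self.lambda_min[-1]),
            "parameter_names": list(self.parameter_names),
            "terminal_log_params": [float(x) for x in self.terminal_log_params],
            "terminal_velocity": [float(x) for x in self.terminal_velocity],
            **self.meta,
        }

    def write_summary(self, path):
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1)


def _calibrate_h(outputs, rho, v, h, y0):
    """One Richardson halving check: shrink h once if A(h) and A(h/2)
    disagree badly (curvature estimate not yet in the O(h^2) regime)."""
    try:
        a1 = directional_second_derivative(outputs, rho, v, h, y0)
        a2 = directional_second_derivative(outputs, rho, v, h / 2, y0)
    except SimulationError:
        return h / 2
    scale = np.max(np.abs(a1)) + np.max(np.abs(a2)) + 1e-30
    if np.max(np.abs(a1 - a2)) / scale > 0.5:
        return h / 2
    return h


def integrate_geodesic(
    output_model,
    rho0,
    options: GeodesicOptions | None = None,
    v0: np.ndarray | None = None,
) -> GeodesicPath:
    """Integrate a geodesic from a calibrated point to a manifold boundary.

    ``output_model`` provides ``outputs(rho)``/``jacobian(rho)`` and
    ``parameter_names``. The initial velocity defaults to the sloppiest
    eigenvector of the metric at ``rho0`` (sign-normalised); if the first
    attempt exhausts the tau budget without reducing the smallest
    eigenvalue, the opposite sign is tried automatically.
    """
    opts = options or GeodesicOptions()
    rho0 = np.asarray(rho0, dtype=float)
    y0, J0 = output_model.jacobian(rho0)
    met0 = metric(J0, output_model.parameter_names)
    auto_v = v0 is None
    if auto_v:
        # Orient the sloppiest eigenvector so its largest-magnitude
        # component points towards zero: limits that remove a term give
        # strictly simpler submodels, so they are explored first. The
        # opposite sign is retried automatically if this stalls.
        v0 = -met0.sloppiest_direction
    path = _integrate_one(output_model, rho0, v0, met0, y0, opts)
    needs_retry = (
        auto_v
        and opts.retry_opposite_sign
        and path.termination in ("tau_max", "no_progress", "solver_failure")
        and path.lambda_min[-1] >= path.lambda_min[0]
    )
    if needs_retry:
        path2 = _integrate_one(output_model, rho0, -v0, met0, y0, opts)
        path2.meta["retried_opposite_sign"] = True
        if path2.termination in ("boundary", "log_cap") or (
            path2.lambda_min[-1] < path.lambda_min[-1]
        ):
            return path2
    return path


def _integrate_one(output_model, rho0, v0, met0, y0, opts: GeodesicOptions):
    n = len(rho0)
    h = _calibrate_h(output_model.outputs, rho0, v0, opts.h, y0)

    def rhs(tau, z):
        rho, v = z[:n], z[n:]
        y, J = output_model.jacobian(rho)
        A = directional_second_derivative(output_model.outputs, rho, v, h, y)
        acc = geodesic_rhs(J, A, opts.rcond)
        return np.concatenate([v, acc])

    taus = [0.0]
    rhos = [rho0.copy()]
    vels = [np.asarray(v0, dtype=float).copy()]
    lams = [met0.lambda_min]
    termination = "tau_max"
    z0 = np.concatenate([rho0, v0])
    try:
        stepper = RK45(
            rhs,
            0.0,
            z0,
            t_bound=opts.tau_max,
            rtol=opts.rtol,
            atol=opts.atol,
            first_step=opts.initial_step,
        )
    except SimulationError:
        return GeodesicPath(
            np.array(taus),
            np.array(rhos),
            np.array(vels),
            np.array(lams),
            tuple(output_model.parameter_names),
            "no_progress",
        )
    steps = 0
    while stepper.status == "running" and steps < opts.max_steps:
        try:
            msg = stepper.step()
        except SimulationError:
            termination = "solver_failure"
            break
        if stepper.status == "failed" or msg not in (None,):
            termination = "solver_failure" if stepper.status == "failed" else termination
            if stepper.status == "failed":
                break
        steps += 1
        z = stepper.y
        rho, v = z[:n], z[n:]
        if opts.renormalize_velocity:
            nv = np.linalg.norm(v)
            if nv > 0:
                v = v / nv
                stepper.y[n:] = v
        try:
            _, J = output_model.jacobian(rho)
            lam = metric(J).lambda_min
        except SimulationError:
            termination = "solver_failure"
            break
        taus.append(stepper.t)
        rhos.append(rho.copy())
        vels.append(v.copy())
        lams.append(lam)
        if lam < opts.eig_threshold:
            termination = "boundary"
            break
        if np.any(np.abs(rho) > opts.log_cap):
            termination = "log_cap"
            break
    else:
        if stepper.status == "finished":
            termination = "tau_max"
    if len(taus) == 1:
        termination = "no_progress" if termination != "solver_failure" else termination
    return GeodesicPath(
        np.array(taus),
        np.array(rhos),
        np.array(vels),
        np.array(lams),
        tuple(output_model.parameter_names),
        termination,
        meta={"h": h, "n_steps": steps},
    )


# ---------------------------------------------------------------------------
# limit classification


@dataclass(frozen=True)
class LimitClassification:
    """Per-parameter verdicts at a manifold boundary.

    verdicts maps parameter name to ``finite``, ``to_zero`` or
    ``to_infinity``; combinations lists proposed new parameters (finite
    ratios/products of diverging parameters) with their terminal values.
    """

    verdicts: dict
    combinations: tuple = ()
    dominance: float = 0.0
    unclassified: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def nonfinite(self) -> tuple:
        return tuple(k for k, v in self.verdicts.items() if v != "finite")


def _tail_drift(path: GeodesicPath, combo: np.ndarray, frac: float = 0.2) -> float:
    """Drift of a log-linear combination over the final stretch of the
    path, normalised by the overall log-parameter excursion."""
    k0 = max(0, int(len(path.taus) * (1 - frac)) - 1)
    series = path.log_params @ combo
    tail = series[k0:]
    total = np.max(np.abs(path.log_params[-1] - path.log_params[0])) + 1e-12
    return float(np.max(np.abs(tail - tail[-1])) / total)


def classify_limit(
    path: GeodesicPath,
    dominance_threshold: float = 0.95,
    drift_tolerance: float = 0.25,
) -> LimitClassification:
    """Read off the boundary limit from the terminal geodesic direction.

    A verdict requires at least ``dominance_threshold`` of the terminal
    unit-velocity mass (sum of squared components) on the implicated
    parameters; otherwise the limit is reported as unclassified with
    diagnostics rather than guessed. For two diverging parameters the
    stability of their log-ratio (or log-product for opposite signs) along
    the path tail decides whether a finite combination is proposed.
    """
    if path.termination not in ("boundary", "log_cap"):
        return LimitClassification(
            {n: "finite" for n in path.parameter_names},
            unclassified=True,
            diagnostics={"reason": f"path terminated with {path.termination!r}"},
        )
    names = path.parameter_names
    v = path.terminal_velocity
    order = np.argsort(-np.abs(v), kind="stable")
    mass = np.cumsum(v[order] ** 2)
    k = int(np.searchsorted(mass, dominance_threshold) + 1)
    k = min(k, len(v))
    implicated = list(order[:k])
    dom = float(mass[k - 1])
    verdicts = {n: "finite" for n in names}
    diagnostics = {
        "terminal_velocity": {n: float(x) for n, x in zip(names, v)},
        "implicated": [names[i] for i in implicated],
        "dominance": dom,
    }
    if dom < dominance_threshold or k > 2:
        return LimitClassification(verdicts, (), dom, True, diagnostics)
    for i in implicated:
        verdicts[names[i]] = "to_infinity" if v[i] > 0 else "to_zero"
    combos = ()
    if k == 2:
        i, j = implicated
        same_sign = v[i] * v[j] > 0
        sign_j = 1.0 if not same_sign else -1.0
        combo = np.zeros(len(v))
        combo[i] = 1.0
        combo[j] = sign_j  # ratio for same sign, product for opposite
        drift = _tail_drift(path, combo)
        diagnostics["combination_drift"] = drift
        if drift < drift_tolerance:
            value = float(np.exp(path.terminal_log_params @ combo))
            kind = "ratio" if same_sign else "product"
            # orient ratios as diverging/diverging, products as the raw
            # product of the zero- and infinity-tending parameters
            if same_sign and v[i] < 0:
                # both to zero: a ratio is still well defined
                pass
            combos = (
                {
                    "kind": kind,
                    "numerator": names[i],
                    "denominator": names[j] if same_sign else None,
                    "partner": None if same_sign else names[j],
                    "params": (names[i], names[j]),
                    "value": value,
                },
            )
        else:
            return LimitClassification(verdicts, (), dom, True, diagnostics)
    return LimitClassification(verdicts, combos, dom, False, diagnostics)
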