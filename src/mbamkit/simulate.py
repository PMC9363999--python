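"""Simulation of state occupancies, currents and parameter sensitivities.

The Markov scheme ``dX/dt = Q(V) X`` is reduced by probability conservation:
the first declared state is eliminated (``x1 = 1 - sum(others)``) and the
remaining occupancies ``u`` obey the affine system ``du/dt = A(V) u + b(V)``.
First-order sensitivities with respect to natural-log parameters are
propagated by the forward sensitivity equations

    dS_k/dt = A S_k + theta_k * (dA/dtheta_k u + db/dtheta_k),

integrated jointly with the states. Integration restarts at every protocol
segment boundary so that voltage steps are never smoothed over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .models import KineticModel, ModelError, ParameterVector, serialize_model
from .protocols import MeasurementSchedule, VoltageProtocol

__all__ = [
    "SolverOptions",
    "SimulationError",
    "CurrentTrace",
    "SensitivityTrace",
    "compile_model",
    "simulate_states",
    "simulate_current",
    "simulate_sensitivities",
    "read_trace_csv",
    "write_trace_csv",
]


class SimulationError(RuntimeError):
    """Recoverable solver failure (overflow from extreme parameters etc.).

    Distinguished from programming errors so that callers such as the
    geodesic integrator or an optimiser can catch it and back off.
    """


@dataclass(frozen=True)
class SolverOptions:
    """Solver settings.

    ``method="auto"`` propagates piecewise-constant (step) segments exactly
    through the eigendecomposition of the constant-coefficient linear system,
    falling back to a stiff ODE solver for ramps or ill-conditioned
    eigenbases. Explicit methods ("LSODA", "BDF") force the ODE-solver path
    everywhere, with absolute and relative tolerances of 1e-8 and a maximum
    step of 0.1 ms by default; ``max_step=None`` lifts the cap, which is safe
    because integration restarts at every segment boundary.
    """

    rtol: float = 1e-8
    atol: float = 1e-8
    max_step: float | None = 0.1
    method: str = "auto"

    @property
    def max_step_value(self) -> float:
        return np.inf if self.max_step is None else self.max_step

    @property
    def ivp_method(self) -> str:
        return "LSODA" if self.method == "auto" else self.method


DEFAULT_SOLVER = SolverOptions()
FAST_SOLVER = SolverOptions(max_step=None)
ODE_SOLVER = SolverOptions(method="LSODA", max_step=None)


@dataclass(frozen=True)
class CurrentTrace:
    """A current trace sampled at strictly increasing times.

    ``provenance`` records model id, parameters, protocol and noise settings
    so a trace can be traced back to the run that produced it.
    """

    times: np.ndarray  # ms
    currents: np.ndarray  # nA
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.currents, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "currents", c)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and currents must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(c))):
            raise ValueError("trace contains non-finite values")


@dataclass(frozen=True)
class SensitivityTrace:
    """Model outputs and the Jacobian d y_m / d log(theta_i)."""

    times: np.ndarray
    outputs: np.ndarray  # (M,)
    jacobian: np.ndarray  # (M, N)
    parameter_names: tuple

    def __post_init__(self):
        if self.jacobian.shape != (len(self.times), len(self.parameter_names)):
            raise ValueError("jacobian must be M x N")
        if not np.all(np.isfinite(self.jacobian)):
            raise ValueError("jacobian contains non-finite values")


# ---------------------------------------------------------------------------
# compiled numeric model


class CompiledModel:
    """Lambdified numeric views of a :class:`KineticModel`."""

    def __init__(self, model: KineticModel):
        self.model = model
        self.param_names = model.parameter_names
        self.states = model.states
        n = len(model.states)
        self.n_states = n
        self.n_dyn = n - 1
        psyms = [sp.Symbol(p, positive=True) for p in self.param_names]
        vsym = sp.Symbol("V", real=True)
        Q = model.rate_matrix_symbolic()
        self._qf = sp.lambdify((vsym, psyms), Q, "numpy")
        usyms = [sp.Symbol(s, nonnegative=True) for s in model.states[1:]]
        x1 = 1 - sum(usyms) if usyms else sp.Integer(1)
        # affine reduced system du/dt = A u + b
        A = Q[1:, 1:] - Q[1:, 0] * sp.ones(1, n - 1)
        b = Q[1:, 0]
        dA = [sp.diff(A, p) for p in psyms]
        db = [sp.diff(b, p) for p in psyms]
        self._af = sp.lambdify((vsym, psyms), A, "numpy")
        self._bf = sp.lambdify((vsym, psyms), b, "numpy")
        self._daf = [sp.lambdify((vsym, psyms), d, "numpy") for d in dA]
        self._dbf = [sp.lambdify((vsym, psyms), d, "numpy") for d in db]
        # observable/current
        subs = {sp.Symbol(model.states[0], nonnegative=True): x1}
        obs = model.observable_symbolic().subs(subs)
        g = sp.Symbol(model.conductance_param, positive=True)
        # 17 significant digits reproduce the float64 reversal potential
        # exactly, so the driving force vanishes identically at V = E_rev
        Ie = g * obs * (vsym - sp.Float(model.reversal_potential, 17))
        self._obsf = sp.lambdify((vsym, psyms, usyms), obs, "numpy")
        self._If = sp.lambdify((vsym, psyms, usyms), Ie, "numpy")
        self._dIdu = [sp.lambdify((vsym, psyms, usyms), sp.diff(Ie, u), "numpy") for u in usyms]
        self._dIdp = [sp.lambdify((vsym, psyms, usyms), sp.diff(Ie, p), "numpy") for p in psyms]

    # -- numeric evaluation ------------------------------------------------

    def rate_matrix(self, v: float, theta: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore"):
            q = np.asarray(self._qf(v, theta), dtype=float)
        if not np.all(np.isfinite(q)):
            raise SimulationError(f"non-finite rate matrix at V={v}")
        return q

    def affine(self, v: float, theta: np.ndarray):
        with np.errstate(over="ignore", invalid="ignore"):
            A = np.asarray(self._af(v, theta), dtype=float)
            b = np.asarray(self._bf(v, theta), dtype=float).reshape(-1)
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
            raise SimulationError(f"non-finite reduced system at V={v}")
        return A, b

    def affine_grads(self, v: float, theta: np.ndarray):
        m = self.n_dyn
        with np.errstate(over="ignore", invalid="ignore"):
            dA = np.stack(
                [np.broadcast_to(np.asarray(f(v, theta), dtype=float), (m, m)) for f in self._daf]
            )
            db = np.stack(
                [
                    np.broadcast_to(np.asarray(f(v, theta), dtype=float).reshape(-1), (m,))
                    for f in self._dbf
                ]
            )
        if not (np.all(np.isfinite(dA)) and np.all(np.isfinite(db))):
            raise SimulationError(f"non-finite parameter gradients at V={v}")
        return dA, db

    def current(self, v, theta, u):
        ulist = [np.asarray(u)[..., k] for k in range(self.n_dyn)]
        with np.errstate(over="ignore", invalid="ignore"):
            out = np.asarray(self._If(v, theta, ulist), dtype=float)
        return out

    def observable(self, v, theta, u):
        ulist = [np.asarray(u)[..., k] for k in range(self.n_dyn)]
        with np.errstate(over="ignore", invalid="ignore"):
            return np.asarray(self._obsf(v, theta, ulist), dtype=float)

    def current_grads(self, v: float, theta: np.ndarray, u: np.ndarray):
        ulist = list(np.asarray(u, dtype=float))
        with np.errstate(over="ignore", invalid="ignore"):
            dIdu = np.array([f(v, theta, ulist) for f in self._dIdu], dtype=float)
            dIdp = np.array([f(v, theta, ulist) for f in self._dIdp], dtype=float)
        return dIdu, dIdp

    def current_vec(self, volts: np.ndarray, theta: np.ndarray, U: np.ndarray):
        """Currents at many (V, u) pairs at once."""
        ulist = [U[:, k] for k in range(self.n_dyn)]
        with np.errstate(over="ignore", invalid="ignore"):
            out = self._If(volts, theta, ulist)
        return np.broadcast_to(np.asarray(out, dtype=float), volts.shape).copy()

    def current_grads_vec(self, volts: np.ndarray, theta: np.ndarray, U: np.ndarray):
        """(dI/du, dI/dtheta) stacked over times: shapes (T, m), (T, npar)."""
        ulist = [U[:, k] for k in range(self.n_dyn)]
        T = len(volts)
        with np.errstate(over="ignore", invalid="ignore"):
            dIdu = np.stack(
                [
                    np.broadcast_to(np.asarray(f(volts, theta, ulist), dtype=float), (T,))
                    for f in self._dIdu
                ],
                axis=1,
            )
            dIdp = np.stack(
                [
                    np.broadcast_to(np.asarray(f(volts, theta, ulist), dtype=float), (T,))
                    for f in self._dIdp
                ],
                axis=1,
            )
        return dIdu, dIdp

    def steady_state_reduced(self, v: float, theta: np.ndarray) -> np.ndarray:
        A, b = self.affine(v, theta)
        try:
            u = np.linalg.solve(A, -b)
        except np.linalg.LinAlgError as exc:
            raise SimulationError(f"singular reduced system at V={v}") from exc
        return u

    def steady_state_sensitivity(self, v: float, theta: np.ndarray) -> np.ndarray:
        """d u_ss / d log(theta), shape (n_dyn, n_params)."""
        A, b = self.affine(v, theta)
        dA, db = self.affine_grads(v, theta)
        u = np.linalg.solve(A, -b)
        rhs = -(dA @ u + db).T * theta[None, :]  # (n_dyn, n_params)
        return np.linalg.solve(A, rhs)


_COMPILE_CACHE: dict = {}


def compile_model(model: KineticModel) -> CompiledModel:
    key = serialize_model(model)
    cm = _COMPILE_CACHE.get(key)
    if cm is None:
        cm = CompiledModel(model)
        _COMPILE_CACHE[key] = cm
    return cm


# ---------------------------------------------------------------------------
# integration helpers


def _theta_array(model: KineticModel, theta) -> np.ndarray:
    if isinstance(theta, ParameterVector):
        arr = theta.to_linear().array(model.parameter_names)
    elif isinstance(theta, dict):
        arr = ParameterVector(theta).array(model.parameter_names)
    else:
        arr = np.asarray(theta, dtype=float)
        if arr.shape != (len(model.parameter_names),):
            raise ModelError(
                f"theta must have {len(model.parameter_names)} entries, got {arr.shape}"
            )
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ModelError("parameters must be finite and strictly positive")
    return arr


_RATE_CAP = 1e14  # beyond this the limit should have been taken symbolically


def _check_magnitude(A: np.ndarray, v: float):
    m = np.max(np.abs(A)) if A.size else 0.0
    if m > _RATE_CAP:
        raise SimulationError(f"rate magnitude {m:.2e} exceeds cap at V={v}")


def _segment_eval_times(times: np.ndarray, t0: float, t1: float, is_last: bool):
    """Times in (t0, t1] (plus t1 itself for continuation)."""
    if is_last:
        mask = (times > t0) & (times <= t1 + 1e-9)
    else:
        mask = (times > t0) & (times <= t1)
    return times[mask]


def _solve_segment(rhs, jac, u0, t0, t1, t_eval, opts: SolverOptions):
    tspan = (t0, t1)
    te = np.unique(np.concatenate([t_eval, [t1]])) if len(t_eval) else np.array([t1])
    with np.errstate(over="ignore", invalid="ignore"):
        sol = solve_ivp(
            rhs,
            tspan,
            u0,
            method=opts.method,
            t_eval=te,
            rtol=opts.rtol,
            atol=opts.atol,
            max_step=opts.max_step_value,
            jac=jac,
        )
    if not sol.success:
        raise SimulationError(f"solver failed on [{t0}, {t1}]: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise SimulationError(f"non-finite solution on [{t0}, {t1}]")
    return te, sol.y.T  # (n_times, dim)


def simulate_states(
    model: KineticModel,
    protocol: VoltageProtocol,
    theta,
    solver_opts: SolverOptions | None = None,
    times=None,
):
    """Solve the state occupancies along a protocol.

    Returns ``(times, X)`` with X of shape (n_times, n_states), rows being
    full occupancy vectors (the eliminated first state is reconstructed as
    ``1 - sum``). The initial condition is the steady state at the holding
    voltage ``protocol.voltage_at(0)``.
    """
    opts = solver_opts or DEFAULT_SOLVER
    cm = compile_model(model)
    th = _theta_array(model, theta)
    if times is None:
        times = np.linspace(0.0, protocol.total_duration, 501)
    times = np.asarray(times, dtype=float)
    u = _run_protocol(cm, protocol, th, times, opts, with_sens=False)
    x1 = 1.0 - u.sum(axis=1)
    X = np.column_stack([x1, u])
    _check_occupancies(X)
    return times, X


class _EigFallback(Exception):
    """Internal: eigen-propagation unreliable here, use the ODE solver."""


def _phi1(lam, dt):
    """(exp(lam*dt) - 1)/lam, elementwise, with the lam -> 0 limit dt."""
    lam = np.asarray(lam)
    small = np.abs(lam * dt) < 1e-12
    safe = np.where(small, 1.0, lam)
    return np.where(small, dt, (np.exp(lam * dt) - 1.0) / safe)


_COND_CAP = 1e9


def _propagate_step(cm, v, th, u0, S0, dts, with_sens):
    """Exact propagation of du/dt = A u + b (and sensitivities) at offsets.

    Uses the eigendecomposition of A; sensitivities use the closed-form
    convolution in the eigenbasis (divided differences of exponentials).
    Raises :class:`_EigFallback` when the eigenbasis is ill-conditioned.
    """
    A, b = cm.affine(v, th)
    _check_magnitude(A, v)
    try:
        lam, W = np.linalg.eig(A)
        Winv = np.linalg.inv(W)
        if np.linalg.cond(W) > _COND_CAP:
            raise _EigFallback
        ustar = np.linalg.solve(A, -b)
    except np.linalg.LinAlgError as exc:
        raise _EigFallback from exc
    dts = np.asarray(dts, dtype=float)
    c = Winv @ (u0 - ustar)
    expl = np.exp(np.outer(dts, lam))  # (T, m)
    U = np.real(ustar[None, :] + expl * c[None, :] @ W.T)
    if not np.all(np.isfinite(U)):
        raise SimulationError(f"non-finite occupancies at V={v}")
    if not with_sens:
        return U, None
    dA, db = cm.affine_grads(v, th)
    dAth = dA * th[:, None, None]
    dbth = db * th[:, None]
    C0 = np.tensordot(dAth, ustar, axes=([2], [0])) + dbth  # (npar, m)
    WS0 = Winv @ S0  # (m, npar)
    WC0 = Winv @ C0.T  # (m, npar)
    B = np.einsum("im,kmn,nj->kij", Winv, dAth, W)  # (npar, m, m)
    # divided differences Phi_ij(t) = (e^{li t} - e^{lj t})/(li - lj)
    dl = lam[:, None] - lam[None, :]
    scale = max(np.max(np.abs(lam)), 1.0)
    degen = np.abs(dl) < 1e-10 * scale
    dl_safe = np.where(degen, 1.0, dl)
    li = lam[:, None]
    lj = lam[None, :]
    T = len(dts)
    eli = np.exp(np.einsum("t,ij->tij", dts, np.broadcast_to(li, dl.shape)))
    elj = np.exp(np.einsum("t,ij->tij", dts, np.broadcast_to(lj, dl.shape)))
    Phi = np.where(
        degen[None, :, :],
        dts[:, None, None] * np.exp(dts[:, None, None] * (li + lj)[None] / 2.0),
        (eli - elj) / dl_safe[None, :, :],
    )
    phi = _phi_matrix(lam, dts)  # (T, m): (e^{l t}-1)/l
    hom = np.einsum("tm,mk->tmk", expl, WS0)
    part = np.einsum("tm,mk->tmk", phi, WC0)
    conv = np.einsum("kij,tij,j->tik", B, Phi, c)  # (T, m, npar)
    S = np.real(np.einsum("im,tmk->tik", W, hom + part + conv))
    if not np.all(np.isfinite(S)):
        raise SimulationError(f"non-finite sensitivities at V={v}")
    return U, S


def _phi_matrix(lam, dts):
    z = np.outer(dts, lam)  # (T, m)
    small = np.abs(z) < 1e-12
    safe = np.where(small, 1.0, lam[None, :])
    return np.where(small, dts[:, None], (np.exp(z) - 1.0) / safe)


def _run_protocol(cm, protocol, th, times, opts, with_sens):
    """Core loop over protocol segments. Returns u(t) at `times`
    (and S(t) stacked if with_sens)."""
    v0 = protocol.voltage_at(0.0)
    m = cm.n_dyn
    npar = len(th)
    u = cm.steady_state_reduced(v0, th)
    S = cm.steady_state_sensitivity(v0, th) if with_sens else None
    dim = m * (npar + 1) if with_sens else m
    bounds = protocol.boundaries
    out = np.empty((len(times), dim))
    filled = np.zeros(len(times), dtype=bool)
    at0 = times <= 0.0
    if at0.any():
        y0 = np.concatenate([u, S.reshape(-1)]) if with_sens else u
        out[at0] = y0
        filled[at0] = True
    for i, seg in enumerate(protocol.segments):
        t0, t1 = bounds[i], bounds[i + 1]
        is_last = i == len(protocol.segments) - 1
        mask = (times > t0) & (times <= (t1 + 1e-9 if is_last else t1)) & ~filled
        idx = np.nonzero(mask)[0]
        te = times[idx]
        done = False
        if opts.method == "auto" and seg.is_step:
            dts = np.concatenate([np.minimum(te - t0, seg.duration), [seg.duration]])
            try:
                U, Ss = _propagate_step(cm, seg.v_start, th, u, S, dts, with_sens)
                rows = np.arange(len(idx))
                done = True
            except _EigFallback:
                done = False
        if not done:
            y = np.concatenate([u, S.reshape(-1)]) if with_sens else u
            rhs, jac = _make_rhs(cm, seg, t0, th, with_sens)
            tgrid, ys = _solve_segment(rhs, jac, y, t0, t1, np.minimum(te, t1), opts)
            rows = np.searchsorted(tgrid, np.minimum(te, t1))
            U = ys[:, :m]
            Ss = ys[:, m:].reshape(len(tgrid), m, npar) if with_sens else None
        if len(idx):
            out[idx, :m] = U[rows]
            if with_sens:
                out[idx, m:] = Ss[rows].reshape(len(idx), -1)
            filled[idx] = True
        # continuation state: last solver row is the segment end
        u = U[-1]
        if with_sens:
            S = Ss[-1]
    if not filled.all():
        missing = times[~filled]
        raise ModelError(f"requested times outside protocol: {missing[:5]}")
    return out


def _make_rhs(cm: CompiledModel, seg, t0: float, th: np.ndarray, with_sens: bool):
    m = cm.n_dyn
    npar = len(th)
    if seg.is_step:
        A, b = cm.affine(seg.v_start, th)
        _check_magnitude(A, seg.v_start)
        if not with_sens:
            return (lambda t, u: A @ u + b), (lambda t, u: A)
        dA, db = cm.affine_grads(seg.v_start, th)
        # forcing F(u) = theta_k * (dA_k u + db_k), shape (m, npar)
        dAth = dA * th[:, None, None]
        dbth = db * th[:, None]
        Jfull = np.kron(np.eye(npar + 1), A)
        for k in range(npar):
            Jfull[m * (k + 1) : m * (k + 2), 0:m] += dAth[k]

        def rhs(t, y):
            u = y[:m]
            S = y[m:].reshape(m, npar)
            du = A @ u + b
            F = (np.tensordot(dAth, u, axes=([2], [0])) + dbth).T
            dS = A @ S + F
            return np.concatenate([du, dS.reshape(-1)])

        return rhs, (lambda t, y: Jfull)
    # ramp segment: voltage varies linearly in time
    dur = seg.duration

    def v_of(t):
        return seg.v_start + (t - t0) / dur * (seg.v_end - seg.v_start)

    if not with_sens:

        def rhs_r(t, u):
            A, b = cm.affine(v_of(t), th)
            return A @ u + b

        return rhs_r, (lambda t, u: cm.affine(v_of(t), th)[0])

    def rhs_rs(t, y):
        v = v_of(t)
        A, b = cm.affine(v, th)
        dA, db = cm.affine_grads(v, th)
        u = y[:m]
        S = y[m:].reshape(m, npar)
        F = (np.tensordot(dA * th[:, None, None], u, axes=([2], [0])) + db * th[:, None]).T
        return np.concatenate([A @ u + b, (A @ S + F).reshape(-1)])

    return rhs_rs, None


_OCC_TOL = 1e-6


def _check_occupancies(X: np.ndarray):
    if np.any(X < -_OCC_TOL) or np.any(X > 1 + _OCC_TOL):
        raise SimulationError(
            f"occupancies outside [0, 1] beyond tolerance: range "
            f"[{X.min():.3e}, {X.max():.3e}]"
        )
    s = X.sum(axis=1)
    if np.any(np.abs(s - 1) > _OCC_TOL):
        raise SimulationError("occupancy sum deviates from 1 beyond tolerance")


def simulate_current(
    model: KineticModel,
    protocol: VoltageProtocol,
    theta,
    schedule: MeasurementSchedule,
    solver_opts: SolverOptions | None = None,
) -> CurrentTrace:
    """Current trace I(t) = g * O(t) * (V(t) - E_rev) at the schedule times."""
    cm = compile_model(model)
    th = _theta_array(model, theta)
    times = schedule.times
    opts = solver_opts or DEFAULT_SOLVER
    u = _run_protocol(cm, protocol, th, times, opts, with_sens=False)
    x1 = 1.0 - u.sum(axis=1)
    _check_occupancies(np.column_stack([x1, u]))
    volts = protocol.voltages(times)
    currents = cm.current_vec(volts, th, u)
    if not np.all(np.isfinite(currents)):
        raise SimulationError("non-finite currents")
    return CurrentTrace(
        times,
        currents,
        provenance={
            "model": model.name,
            "theta": {k: float(v) for k, v in zip(model.parameter_names, th)},
            "n_samples": len(times),
        },
    )


def simulate_sensitivities(
    model: KineticModel,
    protocol: VoltageProtocol,
    theta,
    schedule: MeasurementSchedule,
    solver_opts: SolverOptions | None = None,
) -> SensitivityTrace:
    """Outputs y_m and Jacobian dy_m/dlog(theta_i) via forward sensitivities.

    Parameters absent from a model expression get exactly zero columns. The
    conductance column equals the output itself since I is linear in g.
    """
    cm = compile_model(model)
    th = _theta_array(model, theta)
    times = schedule.times
    opts = solver_opts or FAST_SOLVER
    m, npar = cm.n_dyn, len(th)
    ys = _run_protocol(cm, protocol, th, times, opts, with_sens=True)
    u = ys[:, :m]
    S = ys[:, m:].reshape(len(times), m, npar)
    volts = protocol.voltages(times)
    outputs = cm.current_vec(volts, th, u)
    dIdu, dIdp = cm.current_grads_vec(volts, th, u)
    jac = np.einsum("tm,tmk->tk", dIdu, S) + dIdp * th[None, :]
    if not (np.all(np.isfinite(outputs)) and np.all(np.isfinite(jac))):
        raise SimulationError("non-finite sensitivity outputs")
    return SensitivityTrace(times, outputs, jac, model.parameter_names)


# ---------------------------------------------------------------------------
# trace CSV I/O (columns time_ms, current_nA)


def write_trace_csv(trace: CurrentTrace, path) -> None:
    import pandas as pd

    pd.DataFrame({"time_ms": trace.times, "current_nA": trace.currents}).to_csv(
        path, index=False
    )


def read_trace_csv(path) -> CurrentTrace:
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("time_ms", "current_nA"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing column {col!r}")
    return CurrentTrace(df["time_ms"].to_numpy(), df["current_nA"].to_numpy())
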