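"""Least-squares calibration, mixed-RMS scoring and identifiability.

Fitting minimises the sum-of-squares cost ``C = sum_m (y_m - yhat_m)^2``
over the reference trace's sample times, which under i.i.d. Gaussian
observation noise is the maximum-likelihood estimate. Multi-start bounded
least squares with analytic Jacobians (forward sensitivities) stands in
for the evolutionary-strategy multi-restart scheme commonly used for these
models; prefactor/conductance/combined parameters are optimised in log
space to guarantee positivity, voltage-slope parameters in linear space.

Model-output agreement is scored with the mixed root-mean-square error

    eMRMS = sqrt( mean_t [ (yhat(t) - y(t)) / (1 + |yhat(t)|) ]^2 ),

which blends absolute error (for small currents) and relative error (for
large ones); the reference trace normalises the residuals, so the measure
is deliberately asymmetric. A reduced model is conventionally accepted
while its recalibrated eMRMS stays at or below 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .models import KineticModel, ParameterVector
from .protocols import MeasurementSchedule, VoltageProtocol
from .simulate import (
    CurrentTrace,
    SimulationError,
    SolverOptions,
    simulate_current,
    simulate_sensitivities,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "IdentifiabilityReport",
    "cost",
    "emrms",
    "fit",
    "identifiability_report",
]

EMRMS_THRESHOLD = 0.1  # conventional acceptance threshold for reductions


def cost(
    model: KineticModel,
    protocol: VoltageProtocol,
    theta,
    reference: CurrentTrace,
    solver_opts: SolverOptions | None = None,
) -> float:
    """Sum of squared residuals against the reference at its sample times.

    Solver failures return ``+inf`` (optimiser-safe) rather than raising.
    """
    try:
        tr = simulate_current(
            model, protocol, theta, MeasurementSchedule(tuple(reference.times)), solver_opts
        )
    except SimulationError:
        return float("inf")
    return float(np.sum((tr.currents - reference.currents) ** 2))


def emrms(candidate: CurrentTrace, reference: CurrentTrace) -> float:
    """Mixed root-mean-square error of a candidate against a reference.

    Requires identical (uniformly spaced, conventionally 1 ms) time grids;
    the reference appears in the normalisation, so the measure is not
    symmetric in its arguments.
    """
    if len(candidate.times) != len(reference.times) or not np.allclose(
        candidate.times, reference.times, rtol=0, atol=1e-9
    ):
        raise ValueError("eMRMS requires identical time grids")
    r = (candidate.currents - reference.currents) / (1.0 + np.abs(reference.currents))
    return float(np.sqrt(np.mean(r**2)))


# ---------------------------------------------------------------------------
# multi-start fitting


#: Default search bounds (linear space) by parameter class. Prefactors and
#: conductances span the physiologically plausible decades used in hERG
#: fitting studies; slopes are bounded by the steepest voltage dependence
#: channels display; combined boundary parameters get generous bounds.
DEFAULT_BOUNDS = {
    "prefactor": (1e-7, 1e3),
    "slope": (1e-7, 0.4),
    "conductance": (1e-3, 10.0),
    "combined": (1e-7, 1e3),
}


@dataclass(frozen=True)
class FitOptions:
    """Multi-start settings.

    Each restart is a bounded trust-region least-squares refinement. Start
    points are chosen by scattering ``presample_factor * restarts`` seeded
    samples across the search box, ranking them by initial cost and
    refining from the best ones — the cheap surrogate for a population
    -based global optimiser.
    """

    restarts: int = 50
    seed: int = 1
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    bounds_per_parameter: dict = field(default_factory=dict)
    initial: dict | None = None  # optional warm start included as restart 0
    presample_factor: int = 20
    max_nfev: int = 250
    xtol: float = 1e-10
    ftol: float = 1e-10
    solver_opts: SolverOptions | None = None


@dataclass
class RestartResult:
    index: int
    cost: float
    theta: dict
    success: bool
    message: str
    nfev: int


@dataclass
class FitResult:
    best_theta: ParameterVector
    best_cost: float
    restarts: list
    converged: bool
    parameter_names: tuple

    @property
    def best_restart(self) -> RestartResult:
        return min((r for r in self.restarts if np.isfinite(r.cost)), key=lambda r: r.cost)

    def restart_table(self):
        import pandas as pd

        rows = []
        for r in sorted(self.restarts, key=lambda r: r.cost):
            row = {"restart": r.index, "cost": r.cost, "success": r.success}
            row.update(r.theta)
            rows.append(row)
        return pd.DataFrame(rows)


def _param_bounds(model: KineticModel, opts: FitOptions):
    lo, hi = [], []
    for p in model.parameters:
        b = opts.bounds_per_parameter.get(p.name, opts.bounds.get(p.kind))
        if b is None:
            raise ValueError(f"no bounds for parameter {p.name!r} of kind {p.kind!r}")
        lo.append(b[0])
        hi.append(b[1])
    return np.array(lo), np.array(hi)


def fit(
    model: KineticModel,
    protocol: VoltageProtocol,
    reference: CurrentTrace,
    options: FitOptions | None = None,
) -> FitResult:
    """Multi-start maximum-likelihood (least-squares) calibration.

    Initial guesses are sampled log-uniformly within bounds for
    log-transformed parameters and uniformly for slopes, under a seeded
    generator; every restart's outcome is retained so identifiability can
    be assessed afterwards.
    """
    opts = options or FitOptions()
    rng = np.random.default_rng(opts.seed)
    names = model.parameter_names
    logmask = np.array([p.log_transformed for p in model.parameters])
    lo, hi = _param_bounds(model, opts)
    xlo = np.where(logmask, np.log(lo), lo)
    xhi = np.where(logmask, np.log(hi), hi)
    sched = MeasurementSchedule(tuple(reference.times))
    yref = reference.currents
    penalty = 1e3 * (1.0 + np.max(np.abs(yref)))

    def unpack(x):
        return np.where(logmask, np.exp(x), x)

    def residuals(x):
        try:
            tr = simulate_current(model, protocol, unpack(x), sched, opts.solver_opts)
        except SimulationError:
            return np.full(len(yref), penalty)
        return tr.currents - yref

    def jacobian(x):
        try:
            st = simulate_sensitivities(model, protocol, unpack(x), sched, opts.solver_opts)
        except SimulationError:
            return np.zeros((len(yref), len(x)))
        th = unpack(x)
        J = st.jacobian.copy()  # d y / d log(theta)
        J[:, ~logmask] /= th[~logmask]  # linear-space columns
        return J

    guesses = []
    if opts.initial is not None:
        th0 = ParameterVector(opts.initial).array(names)
        guesses.append(np.where(logmask, np.log(th0), th0))
    n_random = opts.restarts - len(guesses)
    if n_random > 0:
        cand = rng.uniform(xlo, xhi, size=(max(opts.presample_factor, 1) * n_random, len(xlo)))
        scores = np.array([float(np.sum(residuals(x) ** 2)) for x in cand])
        order = np.argsort(scores)
        guesses.extend(cand[order[:n_random]])

    results = []
    for i, x0 in enumerate(guesses):
        try:
            sol = least_squares(
                residuals,
                np.clip(x0, xlo, xhi),
                jac=jacobian,
                bounds=(xlo, xhi),
                method="trf",
                x_scale="jac",
                max_nfev=opts.max_nfev,
                xtol=opts.xtol,
                ftol=opts.ftol,
            )
            th = unpack(sol.x)
            results.append(
                RestartResult(
                    i,
                    float(np.sum(sol.fun**2)) if np.all(np.abs(sol.fun) < penalty) else float("inf"),
                    {k: float(v) for k, v in zip(names, th)},
                    bool(sol.success),
                    str(sol.message),
                    int(sol.nfev),
                )
            )
        except Exception as exc:  # noqa: BLE001 - per-restart diagnostics
            results.append(RestartResult(i, float("inf"), {}, False, repr(exc), 0))
    finite = [r for r in results if np.isfinite(r.cost)]
    if not finite:
        raise SimulationError(
            "all restarts failed: " + "; ".join(r.message for r in results[:5])
        )
    best = min(finite, key=lambda r: r.cost)
    return FitResult(
        best_theta=ParameterVector(best.theta),
        best_cost=best.cost,
        restarts=results,
        converged=best.success,
        parameter_names=names,
    )


# ---------------------------------------------------------------------------
# practical identifiability


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Spread of parameter estimates across the best K restarts.

    A parameter counts as identifiable when its max/min ratio over the K
    lowest-cost restarts stays below the spread threshold; the model is
    identifiable when all parameters are.
    """

    spreads: dict  # name -> max/min ratio (linear space)
    costs: tuple  # rank-ordered costs of the K best restarts
    threshold: float
    per_parameter: dict  # name -> bool

    @property
    def identifiable(self) -> bool:
        return all(self.per_parameter.values())

    @property
    def worst(self):
        name = max(self.spreads, key=self.spreads.get)
        return name, self.spreads[name]


def identifiability_report(
    fit_results, k: int = 30, spread_threshold: float = 2.0
) -> IdentifiabilityReport:
    """Summarise multi-start convergence as a per-parameter spread.

    ``fit_results`` is either a :class:`FitResult` or a list of
    :class:`RestartResult`; the K lowest-cost completed restarts are used.
    """
    if isinstance(fit_results, FitResult):
        restarts = fit_results.restarts
    else:
        restarts = list(fit_results)
    finite = sorted(
        (r for r in restarts if np.isfinite(r.cost) and r.theta), key=lambda r: r.cost
    )
    if len(finite) < k:
        raise ValueError(f"need at least {k} completed restarts, have {len(finite)}")
    top = finite[:k]
    names = top[0].theta.keys()
    spreads = {}
    for n in names:
        vals = np.array([r.theta[n] for r in top])
        spreads[n] = float(vals.max() / vals.min())
    per_param = {n: s < spread_threshold for n, s in spreads.items()}
    return IdentifiabilityReport(
        spreads=spreads,
        costs=tuple(float(r.cost) for r in top),
        threshold=spread_threshold,
        per_parameter=per_param,
    )
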