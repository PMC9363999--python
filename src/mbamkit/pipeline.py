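"""The iterative reduction loop: metric, geodesic, limit, recalibrate.

One iteration of the loop (i) builds the sensitivity metric at the current
calibrated point, (ii) follows a geodesic along the sloppiest direction to
a manifold boundary, (iii) applies the classified limit symbolically and
(iv) recalibrates the reduced model to the original full-model reference
trace. Iterations continue until the recalibrated mixed RMS error exceeds
the acceptance threshold, a limit cannot be classified automatically, or
the iteration budget is reached; the per-iteration ledger is the machine
analogue of a reduction table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .calibrate import EMRMS_THRESHOLD, FitOptions, emrms, fit
from .mbam import GeodesicOptions, KineticOutput, classify_limit, integrate_geodesic
from .models import KineticModel, ParameterVector
from .protocols import VoltageProtocol, uniform_schedule
from .reduce import LimitSpec, NewParameter, UnsupportedLimitError, apply_limit, project_theta
from .simulate import CurrentTrace, simulate_current

__all__ = ["ReductionLoopOptions", "spec_from_classification", "run_reduction_loop"]


@dataclass(frozen=True)
class ReductionLoopOptions:
    emrms_threshold: float = EMRMS_THRESHOLD
    max_iterations: int = 12
    metric_points: int = 37
    calibration_points: int = 5000
    seed: int = 1
    fit_restarts: int = 4
    geodesic: GeodesicOptions = field(default_factory=GeodesicOptions)


def spec_from_classification(classification, iteration: int, label: str) -> LimitSpec:
    """Turn a geodesic limit classification into an applicable LimitSpec.

    New combined parameters are named phi<iteration>.
    """
    if classification.unclassified:
        raise UnsupportedLimitError(
            f"{label}: limit could not be classified automatically "
            f"(diagnostics: {classification.diagnostics})",
        )
    combos = []
    combined_params: set = set()
    for c in classification.combinations:
        name = f"phi{iteration}"
        if c["kind"] == "ratio":
            i, j = c["params"]
            combos.append(NewParameter(name, "ratio", numerator=i, denominator=j))
        else:
            i, j = c["params"]
            inf_p = i if classification.verdicts[i] == "to_infinity" else j
            zero_p = j if inf_p == i else i
            combos.append(NewParameter(name, "product", inf_param=inf_p, zero_param=zero_p))
        combined_params.update(c["params"])
    zeros = tuple(
        k
        for k, v in classification.verdicts.items()
        if v == "to_zero" and k not in combined_params
    )
    infinities = tuple(
        k for k, v in classification.verdicts.items() if v == "to_infinity"
    )
    return LimitSpec(
        label=label, zeros=zeros, infinities=infinities, new_parameters=tuple(combos)
    )


def run_reduction_loop(
    model: KineticModel,
    protocol: VoltageProtocol,
    theta: ParameterVector,
    options: ReductionLoopOptions | None = None,
    outdir=None,
    log=print,
):
    """Run the four-step reduction loop starting from a calibrated model.

    Returns a dict with the per-iteration ledger and the surviving models;
    when ``outdir`` is given, per-iteration artifacts (model JSON, geodesic
    path CSV + summary, ledger) are written there.
    """
    import pathlib

    opts = options or ReductionLoopOptions()
    sched_m = uniform_schedule(protocol, opts.metric_points)
    sched_c = uniform_schedule(protocol, opts.calibration_points)
    reference = simulate_current(model, protocol, theta, sched_c)
    outdir = pathlib.Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    events = []

    def emit(event: dict):
        events.append(event)
        if outdir is not None:
            with open(outdir / "events.jsonl", "a") as fh:
                fh.write(json.dumps(event) + "\n")

    ledger = []
    current, th = model, theta
    for it in range(1, opts.max_iterations + 1):
        names = current.parameter_names
        rho0 = np.log(th.to_linear().array(names))
        out = KineticOutput(current, protocol, sched_m)
        log(f"iteration {it}: geodesic on {current.name} ({len(names)} parameters)")
        path = integrate_geodesic(out, rho0, opts.geodesic)
        if outdir is not None:
            path.write_csv(outdir / f"iter{it:02d}_geodesic.csv")
            path.write_summary(outdir / f"iter{it:02d}_geodesic.json")
        cls = classify_limit(path)
        emit(
            {
                "iteration": it,
                "model": current.name,
                "termination": path.termination,
                "verdicts": {k: v for k, v in cls.verdicts.items() if v != "finite"},
                "unclassified": cls.unclassified,
            }
        )
        label = f"iter{it}: {current.name}"
        try:
            spec = spec_from_classification(cls, it, label)
            reduced = apply_limit(current, spec)
        except UnsupportedLimitError as exc:
            log(f"stopping: {exc}")
            emit({"iteration": it, "stop": str(exc)})
            break
        warm = {
            k: v
            for k, v in project_theta(spec, th).items()
            if k in reduced.parameter_names
        }
        res = fit(
            reduced,
            protocol,
            reference,
            FitOptions(restarts=opts.fit_restarts, seed=opts.seed + it, initial=warm),
        )
        tr = simulate_current(reduced, protocol, res.best_theta, sched_c)
        err = emrms(tr, reference)
        row = {
            "iteration": it,
            "model": reduced.name,
            "limit": spec.label,
            "limit_kind": spec.kind,
            "n_parameters": len(reduced.parameters),
            "n_states": len(reduced.states),
            "emrms": err,
            "cost": res.best_cost,
            "accepted": err <= opts.emrms_threshold,
        }
        ledger.append(row)
        emit(row)
        log(
            f"  -> {spec.label}: {len(reduced.parameters)} parameters, "
            f"eMRMS {err:.4f} ({'accepted' if row['accepted'] else 'rejected'})"
        )
        if outdir is not None:
            from .models import serialize_model

            (outdir / f"iter{it:02d}_model.json").write_text(serialize_model(reduced))
        if err > opts.emrms_threshold:
            break
        current, th = reduced, res.best_theta
    result = {"ledger": ledger, "final_model": current, "final_theta": th, "events": events}
    if outdir is not None:
        with open(outdir / "ledger.json", "w") as fh:
            json.dump(ledger, fh, indent=1)
    return result
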