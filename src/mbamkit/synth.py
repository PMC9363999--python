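"""Synthetic reference traces with the noise structure inference assumes.

Observed currents are modelled as the clean model output plus i.i.d.
Gaussian noise per sample, ``I_data = I_model + eps`` with
``eps ~ N(0, sigma^2)``. The generator here produces such traces from any
kinetic model so that the reduction pipeline and identifiability studies
can run without wet-lab recordings; it does not emulate capacitive
transients, leak or amplifier filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import KineticModel, ParameterVector
from .protocols import MeasurementSchedule, VoltageProtocol
from .simulate import CurrentTrace, SolverOptions, simulate_current

__all__ = ["NoiseModel", "generate_reference", "default_theta", "noise_sigma_for"]

#: Default noise amplitude as a fraction of the peak absolute current.
DEFAULT_NOISE_FRACTION = 0.02


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian noise of standard deviation sigma (nA)."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def generate_reference(
    model: KineticModel,
    protocol: VoltageProtocol,
    theta,
    schedule: MeasurementSchedule,
    noise: NoiseModel = NoiseModel(),
    solver_opts: SolverOptions | None = None,
) -> CurrentTrace:
    """Simulate a current trace and add seeded Gaussian noise.

    With ``sigma = 0`` the clean simulation is returned unchanged, which is
    the default reference for the reduction pipeline; noisy traces are used
    for identifiability studies.
    """
    clean = simulate_current(model, protocol, theta, schedule, solver_opts)
    if noise.sigma == 0.0:
        currents = clean.currents
    else:
        rng = np.random.default_rng(noise.seed)
        currents = clean.currents + rng.normal(0.0, noise.sigma, size=len(clean.currents))
    prov = dict(clean.provenance)
    prov.update({"sigma": noise.sigma, "seed": noise.seed})
    return CurrentTrace(clean.times, currents, prov)


def noise_sigma_for(trace: CurrentTrace, fraction: float = DEFAULT_NOISE_FRACTION) -> float:
    """Noise standard deviation as a fraction of the trace's peak |I|."""
    return float(fraction * np.max(np.abs(trace.currents)))


def default_theta() -> ParameterVector:
    """A documented, physiologically plausible parameter fixture for the
    five-state Wang model.

    Kinetic rates are adapted from the original room-temperature
    formulation of this gating scheme (units ms^-1 and mV^-1), with a
    maximal conductance of 0.1524 uS typical of stable heterologous hERG
    expression; this is a synthetic reference point for the pipeline, not
    a fit to any recording. Under the default protocol it produces clear
    activation at depolarised steps, inactivation at the most positive
    voltages and a large resurgent tail on repolarisation.
    """
    return ParameterVector(
        {
            "p1": 0.013733,
            "p2": 0.038198,
            "p3": 6.89e-05,
            "p4": 0.04178,
            "p5": 0.023761,
            "p6": 0.036778,
            "p7": 0.090821,
            "p8": 0.023391,
            "p9": 0.006497,
            "p10": 0.03268,
            "p11": 0.022348,
            "p12": 0.01176,
            "p13": 0.047002,
            "p14": 0.0631,
            "g": 0.1524,
        }
    )
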