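"""Small analytic output maps for exercising the boundary engine.

These expose the same ``outputs``/``jacobian`` interface as
:class:`mbamkit.mbam.KineticOutput` but with closed-form expressions, so
geodesics and classification can be validated against independent
calculations (and against exhaustive cost-surface mapping at tiny size).
"""

from __future__ import annotations

import numpy as np

__all__ = ["LinearMap", "TwoExponentialMap"]


class LinearMap:
    """y = J0 @ rho + c: a flat manifold; geodesics are straight lines."""

    def __init__(self, J0: np.ndarray, c: np.ndarray | None = None, names=None):
        self.J0 = np.asarray(J0, dtype=float)
        self.c = np.zeros(self.J0.shape[0]) if c is None else np.asarray(c, dtype=float)
        self.parameter_names = tuple(
            names or [f"a{i+1}" for i in range(self.J0.shape[1])]
        )

    def outputs(self, rho):
        return self.J0 @ np.asarray(rho, dtype=float) + self.c

    def jacobian(self, rho):
        return self.outputs(rho), self.J0.copy()


class TwoExponentialMap:
    """y_m = exp(-theta1 t_m) + exp(-theta2 t_m) at fixed sample times.

    The classic sum-of-exponentials example of a sloppy model: its manifold
    boundaries are the coincidence line theta1 = theta2 (rates merge) and
    the faces where one rate escapes to 0 or infinity.
    """

    def __init__(self, times=None):
        self.times = np.asarray(
            times if times is not None else np.linspace(0.2, 4.0, 12), dtype=float
        )
        self.parameter_names = ("theta1", "theta2")

    def outputs(self, rho):
        th = np.exp(np.asarray(rho, dtype=float))
        return np.exp(-th[0] * self.times) + np.exp(-th[1] * self.times)

    def jacobian(self, rho):
        th = np.exp(np.asarray(rho, dtype=float))
        y = self.outputs(rho)
        # d y / d log(theta_i) = -theta_i * t * exp(-theta_i t)
        J = np.column_stack(
            [
                -th[0] * self.times * np.exp(-th[0] * self.times),
                -th[1] * self.times * np.exp(-th[1] * self.times),
            ]
        )
        return y, J
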