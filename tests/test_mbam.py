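"""Metric, second derivatives, geodesics and limit classification."""

import numpy as np
import pytest

from mbamkit import (
    GeodesicOptions,
    classify_limit,
    directional_second_derivative,
    geodesic_rhs,
    integrate_geodesic,
    metric,
)
from mbamkit.mbam import GeodesicPath
from mbamkit.toys import LinearMap, TwoExponentialMap


class TestMetric:
    def test_single_column(self):
        c = np.array([[1.0], [2.0], [3.0]])
        met = metric(c)
        assert met.eigenvalues[0] == pytest.approx(14.0)
        assert met.matrix.shape == (1, 1)

    def test_orthogonal_columns_give_squared_norms(self):
        J = np.array([[3.0, 0.0], [0.0, 2.0], [0.0, 0.0]])
        met = metric(J)
        assert np.allclose(sorted(met.eigenvalues), [4.0, 9.0])

    def test_matches_naive_double_sum(self, rng):
        """g built as J^T J equals the elementwise double loop exactly."""
        J = rng.normal(size=(37, 15))
        met = metric(J)
        naive = np.zeros((15, 15))
        for i in range(15):
            for j in range(15):
                naive[i, j] = sum(J[m, i] * J[m, j] for m in range(37))
        assert np.abs(met.matrix - naive).max() < 1e-12 * np.abs(naive).max()
        assert np.abs(met.matrix - met.matrix.T).max() < 1e-10
        assert met.eigenvalues[-1] >= -1e-10 * met.eigenvalues[0]

    def test_underdetermined_warns(self):
        with pytest.warns(UserWarning, match="rank-deficient"):
            metric(np.ones((3, 5)))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            metric(np.array([[np.inf, 1.0]]))

    def test_sloppiest_direction_sign_convention(self, rng):
        J = rng.normal(size=(20, 4))
        v = metric(J).sloppiest_direction
        assert v[np.argmax(np.abs(v))] > 0
        assert np.linalg.norm(v) == pytest.approx(1.0)


class TestSecondDerivative:
    def test_quadratic_is_exact_for_any_h(self):
        f = lambda r: np.array([r[0] ** 2])
        for h in (1.0, 0.3, 1e-3):
            a = directional_second_derivative(f, np.array([0.7]), np.array([1.0]), h)
            assert a[0] == pytest.approx(2.0, rel=1e-7)

    def test_linear_map_has_zero_curvature(self):
        f = lambda r: np.array([3.0 * r[0] - 2.0 * r[1]])
        a = directional_second_derivative(
            f, np.array([0.1, 0.2]), np.array([1.0, 1.0]) / np.sqrt(2), 1e-2
        )
        assert abs(a[0]) < 1e-9

    def test_matches_analytic_hessian_contraction(self):
        """f(rho) = exp(theta1*theta2) with theta_i = exp(rho_i): the full
        Hessian in log space is analytic, H_ij = (s + s^2) e^s with
        s = theta1*theta2, so v^T H v = 2(s + s^2)e^s for v=(1,1)/sqrt(2)."""
        rho = np.log([0.3, 0.7])
        s = 0.3 * 0.7
        f = lambda r: np.array([np.exp(np.exp(r[0]) * np.exp(r[1]))])
        v = np.array([1.0, 1.0]) / np.sqrt(2)
        # every Hessian entry equals (s + s^2) e^s, so v^T H v scales by
        # sum_ij v_i v_j = (sum_i v_i)^2 = 2
        exact = (s + s**2) * np.exp(s) * np.sum(np.outer(v, v))
        errs = []
        for h in (2e-2, 1e-2):
            a = directional_second_derivative(f, rho, v, h)
            errs.append(abs(a[0] - exact))
        assert errs[0] < 1e-4
        # O(h^2): halving h shrinks the error by about 4
        assert errs[1] < errs[0] / 2.5

    def test_invalid_h(self):
        with pytest.raises(ValueError):
            directional_second_derivative(lambda r: r, np.zeros(1), np.ones(1), 0.0)


class TestGeodesicRhs:
    def test_flat_model_zero_acceleration(self, rng):
        J = rng.normal(size=(10, 3))
        acc = geodesic_rhs(J, np.zeros(10))
        assert np.abs(acc).max() < 1e-12

    def test_scalar_closed_form(self):
        J = np.array([[2.0], [1.0]])
        A = np.array([0.5, -0.3])
        acc = geodesic_rhs(J, A)
        expected = -(J[:, 0] @ A) / (J[:, 0] @ J[:, 0])
        assert acc[0] == pytest.approx(expected)

    def test_matches_independent_two_exponential_implementation(self):
        """Direct, loop-based coding of the geodesic equation with analytic
        first and second log-parameter derivatives of the two-exponential
        map, compared at 10 random states."""
        toy = TwoExponentialMap()
        t = toy.times
        rng = np.random.default_rng(7)
        for _ in range(10):
            rho = rng.uniform(-0.5, 0.5, size=2)
            v = rng.normal(size=2)
            th = np.exp(rho)
            # analytic derivatives wrt rho_i of y = sum_i exp(-th_i t)
            def d1(i):
                return -th[i] * t * np.exp(-th[i] * t)

            def d2(i, j):
                if i != j:
                    return np.zeros_like(t)
                return (-th[i] * t + (th[i] * t) ** 2) * np.exp(-th[i] * t)

            J = np.column_stack([d1(0), d1(1)])
            # Direct double sum for A_m(v) and the acceleration
            A = sum(v[i] * v[j] * d2(i, j) for i in range(2) for j in range(2))
            g = np.zeros((2, 2))
            for i in range(2):
                for j in range(2):
                    g[i, j] = np.sum(J[:, i] * J[:, j])
            direct = -np.linalg.solve(g, J.T @ A)
            package = geodesic_rhs(J, A)
            assert np.abs(package - direct).max() < 1e-8


class TestGeodesicIntegration:
    def test_flat_manifold_straight_line(self):
        lin = LinearMap(np.array([[1.0, 0.3], [0.2, 1.1], [0.5, 0.5]]))
        path = integrate_geodesic(
            lin, np.array([0.3, -0.2]), GeodesicOptions(tau_max=5.0, max_steps=200)
        )
        assert path.termination == "tau_max"  # no boundary on a flat manifold
        assert np.abs(path.velocities - path.velocities[0]).max() < 1e-8
        # collinearity of the traversed points
        d = path.log_params - path.log_params[0]
        if len(d) > 2:
            cross = d[1:, 0] * d[-1, 1] - d[1:, 1] * d[-1, 0]
            assert np.abs(cross).max() < 1e-8

    def test_two_exponential_reaches_rate_merging_boundary(self):
        """From theta = (1, 1.2) the geodesic runs to the fold where the two
        decay rates coincide (the known boundary of this model: it
        degenerates to a single exponential)."""
        toy = TwoExponentialMap()
        path = integrate_geodesic(
            toy,
            np.log([1.0, 1.2]),
            GeodesicOptions(tau_max=200.0, log_cap=12.0, max_steps=1000),
        )
        assert path.termination == "boundary"
        assert path.lambda_min[-1] < 1e-6
        assert path.lambda_min[-1] < path.lambda_min[0]
        r1, r2 = path.terminal_log_params
        assert abs(r1 - r2) < 0.05  # rates have (log-)merged

    def test_failure_before_progress_reported(self):
        class Broken:
            parameter_names = ("a",)

            def outputs(self, rho):
                from mbamkit import SimulationError

                raise SimulationError("nope")

            def jacobian(self, rho):
                return np.zeros(3), np.ones((3, 1))

        path = integrate_geodesic(Broken(), np.zeros(1), GeodesicOptions(max_steps=5))
        assert path.termination in ("no_progress", "solver_failure")
        assert len(path.taus) == 1


def _path(names, rho_start, rho_end, v_end, lam=(1e-3, 1e-8)):
    K = 30
    taus = np.linspace(0, 1, K)
    rhos = np.linspace(rho_start, rho_end, K)
    vels = np.tile(v_end, (K, 1)).astype(float)
    lams = np.geomspace(lam[0], lam[1], K)
    return GeodesicPath(taus, rhos, vels, lams, tuple(names), "boundary")


class TestClassification:
    def test_single_parameter_to_zero(self):
        p = _path(
            ("a", "b", "c"),
            np.zeros(3),
            np.array([-10.0, 0.1, 0.0]),
            np.array([-1.0, 0.0, 0.0]),
        )
        cls = classify_limit(p)
        assert cls.verdicts == {"a": "to_zero", "b": "finite", "c": "finite"}
        assert not cls.unclassified

    def test_ratio_of_two_diverging_parameters(self):
        v = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        p = _path(
            ("a", "b", "c"), np.zeros(3), np.array([8.0, 7.3, 0.0]), v
        )
        cls = classify_limit(p)
        assert cls.verdicts["a"] == "to_infinity"
        assert cls.verdicts["b"] == "to_infinity"
        (combo,) = cls.combinations
        assert combo["kind"] == "ratio"
        assert combo["value"] == pytest.approx(np.exp(8.0 - 7.3))

    def test_product_of_zero_and_infinity(self):
        v = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
        p = _path(("a", "b", "c"), np.zeros(3), np.array([9.0, -9.4, 0.0]), v)
        cls = classify_limit(p)
        assert cls.verdicts["a"] == "to_infinity"
        assert cls.verdicts["b"] == "to_zero"
        (combo,) = cls.combinations
        assert combo["kind"] == "product"
        assert combo["value"] == pytest.approx(np.exp(9.0 - 9.4))

    def test_ambiguous_direction_is_unclassified_not_guessed(self):
        v = np.ones(4) / 2.0
        p = _path(("a", "b", "c", "d"), np.zeros(4), np.ones(4) * 3, v)
        cls = classify_limit(p)
        assert cls.unclassified
        assert set(cls.verdicts.values()) == {"finite"}
        assert "implicated" in cls.diagnostics

    def test_unterminated_path_refused(self):
        p = _path(("a",), np.zeros(1), np.ones(1), np.ones(1))
        p.termination = "tau_max"
        cls = classify_limit(p)
        assert cls.unclassified
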