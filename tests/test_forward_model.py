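"""Forward steady-state Rolie-Poly model: pointwise terms and the solver.

The steady solver is cross-checked against an independent route: stiff
time integration of the full-tensor evolution equation from equilibrium.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from rheoinverse import (
    RoliePolyParams,
    SteadyShearCurve,
    relaxation_term,
    shear_rhs,
    spring_coefficient,
    steady_conformation,
    steady_curve,
    steady_stress_grid,
    stretch_ratio,
    total_steady_stress,
)
from rheoinverse.surrogate import sample_parameter_array

P_REF = RoliePolyParams(eta_p=22.6, tau_D=109.0, tau_R=14.0, chi_max=18.0, beta=13.0)


def integrate_to_steady(p, gamma_dot, t_mult=60.0):
    """Independent oracle: integrate dA/dt from equilibrium to long times."""

    def rhs(_t, y):
        A = np.array([[y[0], y[1], 0.0], [y[1], y[2], 0.0], [0.0, 0.0, y[3]]])
        dA = shear_rhs(A, gamma_dot, p)
        return [dA[0, 0], dA[0, 1], dA[1, 1], dA[2, 2]]

    sol = solve_ivp(
        rhs,
        (0.0, t_mult * max(p.tau_D, p.tau_R)),
        [1.0, 0.0, 1.0, 1.0],
        method="LSODA",
        rtol=1e-11,
        atol=1e-13,
    )
    return sol.y[:, -1]


class TestSpringCoefficient:
    def test_unity_at_equilibrium_stretch(self):
        assert spring_coefficient(1.0, 18.0) == pytest.approx(1.0, abs=0.0)

    def test_reference_value(self):
        # frozen high-precision evaluation of the FENE factor
        assert spring_coefficient(2.0, 18.0) == pytest.approx(1.0062564366632338, rel=1e-12)

    def test_strictly_increasing_and_diverging(self):
        lams = np.linspace(1.0, 17.999, 500)
        ks = spring_coefficient(lams, 18.0)
        assert np.all(np.diff(ks) > 0)
        assert spring_coefficient(17.9999999, 18.0) > 1e6

    @pytest.mark.parametrize("lam", [18.0, 19.0, 0.0, -1.0])
    def test_domain_errors(self, lam):
        with pytest.raises(ValueError):
            spring_coefficient(lam, 18.0)


class TestRelaxationTerm:
    def test_zero_at_equilibrium(self):
        assert np.all(relaxation_term(np.eye(3), P_REF) == 0.0)

    def test_equilibrium_trace_leaves_only_reptation(self):
        # trA = 3 kills the stretch-relaxation factor exactly
        p = RoliePolyParams(1.0, 1.0, 0.1, 18.0, 1.0)
        A = np.diag([1.2, 0.9, 0.9])
        f = relaxation_term(A, p)
        assert f[0, 0] == pytest.approx(-0.2, rel=1e-14)
        assert f[1, 1] == pytest.approx(0.1, rel=1e-14)

    def test_reference_tensor(self):
        # frozen 40-digit evaluation of every component at trA = 3.15
        p = RoliePolyParams(1.0, 1.0, 0.1, 18.0, 1.0)
        A = np.array([[1.3, 0.2, 0.0], [0.2, 0.95, 0.0], [0.0, 0.0, 0.9]])
        f = relaxation_term(A, p)
        assert f[0, 0] == pytest.approx(-1.0677921479458899, rel=1e-12)
        assert f[0, 1] == pytest.approx(-0.39049587075233755, rel=1e-12)
        assert f[1, 1] == pytest.approx(-0.38442437412929923, rel=1e-12)
        assert f[2, 2] == pytest.approx(-0.28680040644121485, rel=1e-12)
        assert f[1, 0] == f[0, 1]

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            B = rng.normal(size=(3, 3)) * 0.3
            A = np.eye(3) + B @ B.T  # symmetric positive definite
            f = relaxation_term(A, P_REF)
            assert np.allclose(f, f.T, rtol=0, atol=0)

    def test_finite_extensibility_guard(self):
        with pytest.raises(ValueError):
            relaxation_term(np.eye(3) * 1.1 * P_REF.chi_max**2, P_REF)


class TestShearRhs:
    def test_equilibrium_at_rest(self):
        assert np.all(shear_rhs(np.eye(3), 0.0, P_REF) == 0.0)

    def test_advective_term_at_equilibrium(self):
        # L·I + I·Lᵀ puts γ̇ in the (x,y) slot and nothing else
        d = shear_rhs(np.eye(3), 2.5, P_REF)
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 2.5
        assert np.allclose(d, expected, rtol=0, atol=1e-15)

    @given(
        axy=st.floats(-0.5, 0.5),
        gd=st.floats(0.01, 100.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_shear_reversal_antisymmetry(self, axy, gd):
        A = np.array([[1.4, axy, 0.0], [axy, 0.9, 0.0], [0.0, 0.0, 0.95]])
        Aneg = A.copy()
        Aneg[0, 1] = Aneg[1, 0] = -axy
        d = shear_rhs(A, gd, P_REF)
        dneg = shear_rhs(Aneg, -gd, P_REF)
        flip = np.diag([1.0, -1.0, 1.0])
        assert np.allclose(dneg, flip @ d @ flip, rtol=1e-12, atol=1e-14)


class TestSteadyState:
    def test_rest_state_is_identity(self):
        assert np.allclose(steady_conformation(P_REF, 0.0), np.eye(3), rtol=0, atol=0)

    def test_matches_time_integration_oracle(self, bounds):
        rng = np.random.default_rng(11)
        theta = sample_parameter_array(bounds, 5, rng)
        for row in theta:
            p = RoliePolyParams.from_free_vector(row)
            gd = 10.0 ** rng.uniform(-4, 4)
            A = steady_conformation(p, gd)
            y = integrate_to_steady(p, gd)
            got = np.array([A[0, 0], A[0, 1], A[1, 1], A[2, 2]])
            assert np.max(np.abs(got - y)) / np.max(np.abs(y)) < 1e-6

    def test_transverse_isotropy_and_positive_definiteness(self, bounds):
        rng = np.random.default_rng(3)
        for row in sample_parameter_array(bounds, 5, rng):
            p = RoliePolyParams.from_free_vector(row)
            for gd in [1e-3, 1.0, 1e4]:
                A = steady_conformation(p, gd)
                assert A[1, 1] == pytest.approx(A[2, 2], rel=1e-12)
                assert np.all(np.linalg.eigvalsh(A) > 0)
                assert np.trace(A) < 3 * p.chi_max**2
                assert stretch_ratio(A) < p.chi_max

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            steady_conformation(P_REF, -1.0)


class TestSteadyStress:
    def test_zero_shear_viscosity_limit(self):
        gd = 1e-6 / P_REF.tau_D
        s, _ = total_steady_stress(P_REF, gd)
        assert s / gd == pytest.approx(P_REF.eta_s + P_REF.eta_p, rel=1e-9)

    def test_zero_shear_first_normal_stress_limit(self):
        gd = 1e-6 / P_REF.tau_D
        _, n1 = total_steady_stress(P_REF, gd)
        assert n1 / gd**2 == pytest.approx(2 * P_REF.eta_p * P_REF.tau_D, rel=1e-3)

    def test_signs_along_curve(self, rates91):
        c = steady_curve(P_REF, rates91)
        assert np.all(c.sigma_xy > 0)
        assert np.all(c.N1 > 0)
        assert len(c) == 91


class TestSteadyCurve:
    def test_single_zero_rate(self):
        c = steady_curve(P_REF, [0.0])
        assert c.sigma_xy[0] == 0.0 and c.N1[0] == 0.0

    def test_stateless_under_sweep_splitting(self, rates91):
        full = steady_curve(P_REF, rates91)
        first = steady_curve(P_REF, rates91[:40])
        second = steady_curve(P_REF, rates91[40:])
        merged_sigma = np.concatenate([first.sigma_xy, second.sigma_xy])
        merged_n1 = np.concatenate([first.N1, second.N1])
        assert np.allclose(full.sigma_xy, merged_sigma, rtol=1e-9)
        assert np.allclose(full.N1, merged_n1, rtol=1e-9)

    def test_rejects_unsorted_rates(self):
        with pytest.raises(ValueError):
            steady_curve(P_REF, [1.0, 0.5])

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            SteadyShearCurve(np.array([-1.0, 2.0]), np.ones(2), np.ones(2))


class TestStressGrid:
    def test_grid_matches_per_set_curves(self, bounds, rates91):
        rng = np.random.default_rng(21)
        theta = sample_parameter_array(bounds, 4, rng)
        sigma, n1 = steady_stress_grid(theta, rates91, P_REF.eta_s, P_REF.delta)
        for i in range(4):
            c = steady_curve(RoliePolyParams.from_free_vector(theta[i]), rates91)
            assert np.allclose(sigma[i], c.sigma_xy, rtol=1e-8)
            assert np.allclose(n1[i], c.N1, rtol=1e-8)
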