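"""Steady-state Rolie-Poly constitutive model under simple shear.

The single-mode Rolie-Poly ("ROuse LInear Entangled POLYmers") model evolves
the polymer conformation tensor A (normalized so A = I at equilibrium) as

    dA/dt = L·A + A·Lᵀ + f(A),

with the non-Gaussian (finite-extensibility) relaxation function

    f(A) = −(1/τD)(A − I)
           − (2/τR) ks(λ) (1 − √(3/trA)) [A + β (trA/3)^δ (A − I)],

where λ = √(trA/3) is the chain stretch ratio and ks(λ) is the FENE-type
nonlinear spring factor that diverges as λ → χmax.  The polymeric stress is
σp = G ks(λ) (A − I) with plateau modulus G = ηp/τD, and the total stress
adds the Newtonian solvent part 2 ηs D.

Simple shear uses the velocity field u = (γ̇ y, 0, 0), i.e. the velocity
gradient L_ij = ∂u_i/∂x_j has γ̇ in the (x, y) slot and zeros elsewhere.
Under this convention the advective term contributes 2γ̇ A_xy to the xx
equation and γ̇ A_yy to the xy equation.

The steady state is found by damped Newton iteration on the reduced
three-component system (A_xx, A_xy, A_yy) — the yy and zz equations are
identical, so A_zz = A_yy on the physical branch — with warm-start
continuation along the shear-rate sweep and an adaptive stiff pseudo-time
integration as fallback.  The physical root is selected by continuation
from the equilibrium branch A = I.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import RoliePolyParams

__all__ = [
    "SteadyShearCurve",
    "SteadyStateError",
    "spring_coefficient",
    "stretch_ratio",
    "relaxation_term",
    "shear_rhs",
    "steady_conformation",
    "total_steady_stress",
    "steady_curve",
    "steady_stress_grid",
]

#: Default tolerance on the scaled steady-state residual (max-norm).
RESIDUAL_TOL = 1.0e-10

#: Safety margin keeping tr A strictly below the finite-extensibility bound.
_TR_MARGIN = 1.0 - 1.0e-12


class SteadyStateError(RuntimeError):
    """Steady-state solve failed after all fallbacks.

    Carries the shear rate, parameter set and last iterate for diagnosis.
    """

    def __init__(self, message: str, diagnostics: dict[str, Any] | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# ---------------------------------------------------------------------------
# Pointwise model functions (full-tensor form)
# ---------------------------------------------------------------------------

def spring_coefficient(lam, chi_max):
    """FENE-type nonlinear spring factor ks(λ).

        ks(λ) = [(3 − λ²/χmax²)(1 − 1/χmax²)] / [(1 − λ²/χmax²)(3 − 1/χmax²)]

    ks(1) = 1 exactly, ks is strictly increasing on (1, χmax) and diverges as
    the stretch ratio approaches the finite-extensibility limit χmax.

    Accepts scalars or arrays for ``lam``; raises ``ValueError`` outside the
    domain 0 < λ < χmax.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0.0) or np.any(lam_arr >= chi_max):
        raise ValueError(f"stretch ratio must lie in (0, chi_max={chi_max}), got {lam!r}")
    r = (lam_arr / chi_max) ** 2
    r1 = 1.0 / chi_max**2
    out = ((3.0 - r) * (1.0 - r1)) / ((1.0 - r) * (3.0 - r1))
    return out if out.ndim else float(out)


def stretch_ratio(A: np.ndarray) -> float:
    """Chain stretch ratio λ = √(trA/3) of a conformation tensor."""
    return float(np.sqrt(np.trace(np.asarray(A, dtype=float)) / 3.0))


def _check_conformation(A: np.ndarray, p: RoliePolyParams) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.shape != (3, 3):
        raise ValueError(f"conformation tensor must be 3x3, got shape {A.shape}")
    tr = np.trace(A)
    if tr >= 3.0 * p.chi_max**2:
        raise ValueError(
            f"trA = {tr} violates the finite-extensibility bound 3*chi_max^2 = {3.0 * p.chi_max**2}"
        )
    return A


def relaxation_term(A: np.ndarray, p: RoliePolyParams) -> np.ndarray:
    """Relaxation function f(A): reptation + CCR/stretch relaxation.

    Symmetric whenever A is; f(I) = 0 exactly.
    """
    A = _check_conformation(A, p)
    I = np.eye(3)
    tr = np.trace(A)
    lam = np.sqrt(tr / 3.0)
    ks = spring_coefficient(lam, p.chi_max)
    phi = 1.0 - np.sqrt(3.0 / tr)
    psi = (tr / 3.0) ** p.delta
    return (
        -(A - I) / p.tau_D
        - (2.0 / p.tau_R) * ks * phi * (A + p.beta * psi * (A - I))
    )


def shear_rhs(A: np.ndarray, gamma_dot: float, p: RoliePolyParams) -> np.ndarray:
    """Full conformation evolution rate dA/dt = L·A + A·Lᵀ + f(A) in simple shear."""
    A = _check_conformation(A, p)
    L = np.zeros((3, 3))
    L[0, 1] = gamma_dot
    return L @ A + A @ L.T + relaxation_term(A, p)


# ---------------------------------------------------------------------------
# Reduced steady-state system (A_xx, A_xy, A_yy), vectorized
# ---------------------------------------------------------------------------

def _resid_jac(axx, axy, ayy, gd, tau_D, tau_R, chi2, beta, delta, want_jac=True):
    """Residual (and Jacobian) of the reduced steady-state equations.

    All arguments broadcast; returns (R, J, scale) where R stacks the xx, xy,
    yy residuals on the last axis, J is the 3x3 Jacobian w.r.t. (axx, axy,
    ayy), and ``scale`` is a positive local rate scale used to normalize the
    residual norm across shear-rate and stretch regimes.
    """
    t = axx + 2.0 * ayy
    u = t / (3.0 * chi2)
    C = (1.0 - 1.0 / chi2) / (3.0 - 1.0 / chi2)
    one_m_u = 1.0 - u
    ks = C * (3.0 - u) / one_m_u
    phi = 1.0 - np.sqrt(3.0 / t)
    psi = (t / 3.0) ** delta
    h = (2.0 / tau_R) * ks * phi
    bp = beta * psi
    P1 = axx + bp * (axx - 1.0)
    P2 = axy * (1.0 + bp)
    P3 = ayy + bp * (ayy - 1.0)
    inv_tD = 1.0 / tau_D
    R = np.stack(
        [
            2.0 * gd * axy - (axx - 1.0) * inv_tD - h * P1,
            gd * ayy - axy * inv_tD - h * P2,
            -(ayy - 1.0) * inv_tD - h * P3,
        ],
        axis=-1,
    )
    scale = (inv_tD + np.abs(h) * (1.0 + np.abs(bp)) + np.abs(gd)) * (1.0 + t)
    if not want_jac:
        return R, None, scale
    dks_dt = 2.0 * C / (one_m_u**2 * 3.0 * chi2)
    dphi_dt = 0.5 * np.sqrt(3.0) * t**-1.5
    dpsi_dt = delta * psi / t
    dh_dt = (2.0 / tau_R) * (dks_dt * phi + ks * dphi_dt)
    G1 = dh_dt * P1 + h * beta * dpsi_dt * (axx - 1.0)
    G2 = dh_dt * P2 + h * beta * dpsi_dt * axy
    G3 = dh_dt * P3 + h * beta * dpsi_dt * (ayy - 1.0)
    q = inv_tD + h * (1.0 + bp)
    z = np.zeros(np.broadcast(axx, gd).shape)
    J = np.stack(
        [
            np.stack([-q - G1, 2.0 * gd + z, -2.0 * G1], axis=-1),
            np.stack([-G2, -q + z, gd - 2.0 * G2], axis=-1),
            np.stack([-G3, z, -q - 2.0 * G3], axis=-1),
        ],
        axis=-2,
    )
    return R, J, scale


def _solve3(J, b):
    """Batched 3x3 linear solve by Cramer's rule (last two axes of J)."""
    a11, a12, a13 = J[..., 0, 0], J[..., 0, 1], J[..., 0, 2]
    a21, a22, a23 = J[..., 1, 0], J[..., 1, 1], J[..., 1, 2]
    a31, a32, a33 = J[..., 2, 0], J[..., 2, 1], J[..., 2, 2]
    c11 = a22 * a33 - a23 * a32
    c12 = a23 * a31 - a21 * a33
    c13 = a21 * a32 - a22 * a31
    det = a11 * c11 + a12 * c12 + a13 * c13
    b1, b2, b3 = b[..., 0], b[..., 1], b[..., 2]
    x1 = b1 * c11 + b2 * (a13 * a32 - a12 * a33) + b3 * (a12 * a23 - a13 * a22)
    x2 = b1 * c12 + b2 * (a11 * a33 - a13 * a31) + b3 * (a13 * a21 - a11 * a23)
    x3 = b1 * c13 + b2 * (a12 * a31 - a11 * a32) + b3 * (a11 * a22 - a12 * a21)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / det
    return np.stack([x1 * inv, x2 * inv, x3 * inv], axis=-1)


def _physical(y, chi2):
    """Mask of states inside the physical domain (PD, below the FENE bound)."""
    axx, axy, ayy = y[..., 0], y[..., 1], y[..., 2]
    t = axx + 2.0 * ayy
    return (
        (axx > 0.0)
        & (ayy > 0.0)
        & (t < 3.0 * chi2 * _TR_MARGIN)
        & (axx * ayy - axy**2 > 0.0)
    )


def _newton_batch(y0, gd, pvec, tol=RESIDUAL_TOL, max_iter=60):
    """Damped Newton on the reduced system, batched over the leading axis.

    Returns (y, converged_mask).  Steps are backtracked to stay inside the
    physical domain and to enforce residual decrease; iteration continues
    past ``tol`` toward the round-off floor so low-rate normal-stress
    differences (O(γ̇²) departures from I) are fully resolved.
    """
    tau_D, tau_R, chi2, beta, delta = pvec
    y = np.array(y0, dtype=float)
    gd = np.broadcast_to(np.asarray(gd, dtype=float), y.shape[:-1]).copy()
    floor = min(tol, 1.0e-13)
    R, _, sc = _resid_jac(y[..., 0], y[..., 1], y[..., 2], gd, tau_D, tau_R, chi2, beta, delta, want_jac=False)
    rn = np.max(np.abs(R), axis=-1) / sc
    active = rn > floor
    stall = np.zeros(y.shape[:-1], dtype=int)
    for _ in range(max_iter):
        if not np.any(active):
            break
        R, J, sc = _resid_jac(y[..., 0], y[..., 1], y[..., 2], gd, tau_D, tau_R, chi2, beta, delta)
        step = _solve3(J, -R)
        step = np.where(np.isfinite(step), step, 0.0)
        step[~active] = 0.0
        alpha = np.where(active, 1.0, 0.0)
        # shrink into the physical domain
        for _ in range(60):
            cand = y + alpha[..., None] * step
            bad = active & ~_physical(cand, chi2)
            if not np.any(bad):
                break
            alpha[bad] *= 0.5
        # backtrack on the scaled residual norm
        for _ in range(15):
            cand = y + alpha[..., None] * step
            Rc, _, scc = _resid_jac(cand[..., 0], cand[..., 1], cand[..., 2], gd, tau_D, tau_R, chi2, beta, delta, want_jac=False)
            rc = np.max(np.abs(Rc), axis=-1) / scc
            reject = active & (rc > rn * (1.0 - 1.0e-4 * alpha)) & (rc > floor) & (alpha > 1.0e-8)
            if not np.any(reject):
                break
            alpha[reject] *= 0.5
        improved = rc < rn
        stall = np.where(active & ~improved, stall + 1, 0)
        take = active & (improved | (stall < 2))
        y = np.where(take[..., None], cand, y)
        rn = np.where(take, rc, rn)
        active = active & (rn > floor) & (stall < 2)
    return y, rn <= tol


def _pvec_of(p: RoliePolyParams):
    return (p.tau_D, p.tau_R, p.chi_max**2, p.beta, p.delta)


def _plausible(y, gd):
    """Reject converged-but-spurious roots: the physical branch reached by
    continuation from equilibrium has A_xy ≥ 0 for γ̇ ≥ 0 and A_yy bounded
    away from the degenerate A_yy → 0 root."""
    return (y[..., 1] >= -1.0e-12) & (y[..., 2] > 1.0e-8)


def _pseudo_time_single(y0, gd, p: RoliePolyParams, tol):
    """Stiff pseudo-time integration of the reduced system to steady state."""
    pv = _pvec_of(p)

    def rhs(_t, y):
        R, _, _ = _resid_jac(y[0], y[1], y[2], gd, *pv, want_jac=False)
        return R

    t_end = 60.0 * max(p.tau_D, p.tau_R)
    sol = solve_ivp(rhs, (0.0, t_end), np.asarray(y0, dtype=float), method="LSODA", rtol=1.0e-10, atol=1.0e-12)
    y = sol.y[:, -1]
    y2, ok = _newton_batch(y[None, :], np.array([gd]), pv, tol=tol)
    return y2[0], bool(ok[0])


def _solve_single_with_substeps(y_start, gd_start, gd_target, p, tol, max_splits=6):
    """Continuation from a converged state at gd_start up to gd_target.

    The continuation ladder is geometric in γ̇, starting near-equilibrium
    (Wi ≈ 0.01) when no converged lower-rate state is available; its density
    doubles on failure.  Falls back to stiff pseudo-time integration.
    """
    pv = _pvec_of(p)
    y0 = np.array(y_start, dtype=float)
    lo = gd_start
    if gd_start <= 0.0:
        lo = min(gd_target, 0.01 / max(p.tau_D, p.tau_R))
        y0 = np.array([1.0, 0.0, 1.0])
    n_sub = max(1, int(np.ceil(2.0 * np.log10(max(gd_target / lo, 1.0 + 1.0e-12)))))
    for _ in range(max_splits):
        y = y0.copy()
        ladder = np.geomspace(lo, gd_target, n_sub + 1)[1:]
        ok = True
        for g in ladder:
            y_new, conv = _newton_batch(y[None, :], np.array([g]), pv, tol=tol)
            if not (conv[0] and _plausible(y_new, g)[0]):
                ok = False
                break
            y = y_new[0]
        if ok:
            return y, True
        n_sub *= 2
    y, ok = _pseudo_time_single(y0, gd_target, p, tol)
    return y, ok and bool(_plausible(y[None, :], gd_target)[0])


def _steady_reduced(p: RoliePolyParams, rates: np.ndarray, init: np.ndarray | None, tol: float) -> np.ndarray:
    """Steady reduced states (A_xx, A_xy, A_yy), one row per shear rate.

    With ``init`` given (a previous solution at nearby parameters) all rates
    are solved in one batched Newton pass; otherwise the sweep warm-starts
    each rate by continuation from the previous one, beginning at the
    equilibrium branch.
    """
    rates = np.asarray(rates, dtype=float)
    pv = _pvec_of(p)
    n = rates.size
    Y = np.empty((n, 3))
    eq = np.array([1.0, 0.0, 1.0])
    zero = rates <= 0.0
    Y[zero] = eq
    idx = np.nonzero(~zero)[0]
    if idx.size == 0:
        return Y
    if init is not None:
        y0 = np.asarray(init, dtype=float)[idx]
        y0 = np.where(_physical(y0, p.chi_max**2)[..., None], y0, eq)
        y, ok = _newton_batch(y0, rates[idx], pv, tol=tol)
        ok = ok & _plausible(y, rates[idx])
        Y[idx] = y
        bad = idx[~ok]
    else:
        bad = idx
    if init is None or bad.size:
        # sequential warm-start sweep over the (remaining) rates
        prev_y, prev_g = eq, 0.0
        targets = idx if init is None else bad
        targets = np.sort(targets)
        wi_scale = max(p.tau_D, p.tau_R)
        for k in idx:
            if k not in targets:
                prev_y, prev_g = Y[k], rates[k]
                continue
            big_jump = (prev_g <= 0.0 and rates[k] * wi_scale > 0.5) or (
                prev_g > 0.0 and rates[k] > 10.0 * prev_g
            )
            ok1 = np.array([False])
            if not big_jump:
                y, ok1 = _newton_batch(prev_y[None, :], rates[k : k + 1], pv, tol=tol)
                ok1 = ok1 & _plausible(y, rates[k])
            if ok1[0]:
                Y[k] = y[0]
            else:
                y1, ok2 = _solve_single_with_substeps(prev_y, prev_g, rates[k], p, tol)
                if not ok2:
                    raise SteadyStateError(
                        f"steady-state solve failed at shear rate {rates[k]:g} 1/s",
                        {"params": p.to_dict(), "gamma_dot": float(rates[k]), "last_iterate": y1},
                    )
                Y[k] = y1
            prev_y, prev_g = Y[k], rates[k]
    return Y


def _stress_from_reduced(p_eta_p, tau_D, eta_s, chi2, Y, rates):
    """(σxy, N1) from reduced steady states; broadcasts over leading axes."""
    axx, axy, ayy = Y[..., 0], Y[..., 1], Y[..., 2]
    t = axx + 2.0 * ayy
    u = t / (3.0 * chi2)
    ks = ((3.0 - u) * (1.0 - 1.0 / chi2)) / ((1.0 - u) * (3.0 - 1.0 / chi2))
    G = p_eta_p / tau_D
    sigma_xy = eta_s * rates + G * ks * axy
    N1 = G * ks * (axx - ayy)
    return sigma_xy, N1


# ---------------------------------------------------------------------------
# Public steady-state API
# ---------------------------------------------------------------------------

def steady_conformation(p: RoliePolyParams, gamma_dot: float, tol: float = RESIDUAL_TOL) -> np.ndarray:
    """Steady conformation tensor A* (full 3x3) at one shear rate.

    γ̇ = 0 returns the identity.  The physical root is reached by
    continuation from equilibrium; A_zz = A_yy on this branch.
    """
    if gamma_dot < 0.0:
        raise ValueError("gamma_dot must be nonnegative; use shear-reversal symmetry for negative rates")
    Y = _steady_reduced(p, np.array([gamma_dot]), None, tol)[0]
    A = np.diag([Y[0], Y[2], Y[2]])
    A[0, 1] = A[1, 0] = Y[1]
    return A


def total_steady_stress(p: RoliePolyParams, gamma_dot: float, tol: float = RESIDUAL_TOL) -> tuple[float, float]:
    """Total steady shear stress σxy and first normal stress difference N1 [Pa].

    σxy = ηs γ̇ + G ks(λ*) A*xy and N1 = G ks(λ*) (A*xx − A*yy); the solvent
    is Newtonian and contributes nothing to N1.
    """
    Y = _steady_reduced(p, np.array([gamma_dot]), None, tol)
    s, n1 = _stress_from_reduced(p.eta_p, p.tau_D, p.eta_s, p.chi_max**2, Y, np.array([gamma_dot]))
    return float(s[0]), float(n1[0])


@dataclass
class SteadyShearCurve:
    """A steady shear flow curve: (γ̇ [1/s], σxy [Pa], N1 [Pa]) over a rate sweep."""

    gamma_dot: np.ndarray
    sigma_xy: np.ndarray
    N1: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gamma_dot = np.asarray(self.gamma_dot, dtype=float)
        self.sigma_xy = np.asarray(self.sigma_xy, dtype=float)
        self.N1 = np.asarray(self.N1, dtype=float)
        if not (self.gamma_dot.shape == self.sigma_xy.shape == self.N1.shape):
            raise ValueError("gamma_dot, sigma_xy and N1 must have identical shapes")
        if self.gamma_dot.ndim != 1:
            raise ValueError("curve arrays must be one-dimensional")
        if np.any(self.gamma_dot < 0.0):
            raise ValueError("shear rates must be nonnegative")
        if self.gamma_dot.size > 1 and np.any(np.diff(self.gamma_dot) <= 0.0):
            raise ValueError("shear rates must be strictly increasing")

    def __len__(self) -> int:
        return self.gamma_dot.size

    def stresses(self) -> np.ndarray:
        """Stack (σxy, N1) into an (M, 2) array."""
        return np.column_stack([self.sigma_xy, self.N1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"shear_rate": self.gamma_dot, "sigma_xy": self.sigma_xy, "N1": self.N1}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict[str, Any] | None = None) -> "SteadyShearCurve":
        return cls(
            df["shear_rate"].to_numpy(),
            df["sigma_xy"].to_numpy(),
            df["N1"].to_numpy(),
            metadata=dict(metadata or {}),
        )


def log_rate_grid(lo_log10: float = -4.0, hi_log10: float = 4.0, n: int = 91) -> np.ndarray:
    """The canonical rate sweep: n points log-uniform on [10^lo, 10^hi] 1/s."""
    return np.logspace(lo_log10, hi_log10, n)


def steady_curve(
    p: RoliePolyParams,
    rates: Sequence[float],
    tol: float = RESIDUAL_TOL,
    metadata: dict[str, Any] | None = None,
) -> SteadyShearCurve:
    """Compute the steady flow curve over an ascending rate sweep.

    Uses warm-start continuation from each previous rate; the result is
    stateless (independent of how the sweep is split across calls).
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size and rates.min() < 0.0:
        raise ValueError("shear rates must be nonnegative")
    if rates.size > 1 and np.any(np.diff(rates) <= 0.0):
        raise ValueError("shear rates must be strictly increasing")
    Y = _steady_reduced(p, rates, None, tol)
    s, n1 = _stress_from_reduced(p.eta_p, p.tau_D, p.eta_s, p.chi_max**2, Y, rates)
    return SteadyShearCurve(rates, s, n1, metadata=dict(metadata or {}))


def steady_stress_grid(
    theta: np.ndarray,
    rates: Sequence[float],
    eta_s: float,
    delta: float,
    tol: float = RESIDUAL_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady (σxy, N1) for many parameter sets on a shared rate grid.

    ``theta`` is (n, 5) in canonical free-parameter order.  The solve is
    batched across parameter sets and swept over ascending rates with warm
    starts, which makes bulk training-set generation fast.  Returns
    (sigma, N1) of shape (n, M).
    """
    theta = np.asarray(theta, dtype=float)
    rates = np.asarray(rates, dtype=float)
    n = theta.shape[0]
    eta_p, tau_D, tau_R, chi_max, beta = (theta[:, i] for i in range(5))
    pv = (tau_D, tau_R, chi_max**2, beta, delta)
    sigma = np.empty((n, rates.size))
    N1 = np.empty((n, rates.size))
    y = np.tile(np.array([1.0, 0.0, 1.0]), (n, 1))
    for j, g in enumerate(rates):
        if g <= 0.0:
            y = np.tile(np.array([1.0, 0.0, 1.0]), (n, 1))
            sigma[:, j] = 0.0
            N1[:, j] = 0.0
            continue
        y, ok = _newton_batch(y, np.full(n, g), pv, tol=tol)
        ok = ok & _plausible(y, g)
        if not np.all(ok):
            for i in np.nonzero(~ok)[0]:
                p_i = RoliePolyParams.from_free_vector(theta[i], eta_s=eta_s, delta=delta)
                y_i, ok_i = _solve_single_with_substeps(np.array([1.0, 0.0, 1.0]), 0.0, g, p_i, tol)
                if not ok_i:
                    raise SteadyStateError(
                        f"steady-state solve failed for parameter set {i} at rate {g:g} 1/s",
                        {"params": p_i.to_dict(), "gamma_dot": float(g)},
                    )
                y[i] = y_i
        s_j, n1_j = _stress_from_reduced(eta_p, tau_D, eta_s, chi_max**2, y, g)
        sigma[:, j] = s_j
        N1[:, j] = n1_j
    return sigma, N1
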