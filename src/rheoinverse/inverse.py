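"""Bounded gradient-descent inverse solver for molecular parameters.

The solver searches unconstrained trial coordinates ω = (ω1..ω5), one per
free parameter, mapped into the admissible box through a sigmoid:

    θ̂i = (Maxθi − Minθi) g(ωi) + Minθi,   g(ω) = 1 / (1 + e^−ω),

so every trial parameter set stays strictly inside its bounds.  The misfit
between predicted and observed stresses is the mean relative error

    Error(ω) = (1/2M) Σ_j Σ_{c ∈ {σxy, N1}} |σ̂_c(γ̇_j; ω) − σ_c,data(γ̇_j)| / σ_c,data(γ̇_j)

over the M shear rates of the input curve, minimized by plain gradient
descent ω ← ω − ρ ∇ω Error with a step size ρ that decays by a fixed factor
whenever the error has nearly saturated.  Iteration stops when the update
max-norm falls below ε.  Several independent random restarts probe the
dependence on the initial trial point; results are aggregated as mean ± SD
over converged restarts.

Two interchangeable prediction backends are provided:

* ``"surrogate"`` — the trained neural network; gradients flow analytically
  through the network and the sigmoid map (reverse-mode differentiation).
* ``"direct"`` — the steady-state Rolie-Poly solver itself; gradients come
  from implicit-function-theorem sensitivities of the steady state (or
  finite differences on ω as a cross-check).  This backend decouples
  inverse-solver correctness from surrogate quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

import numpy as np

from .forward_model import (
    RESIDUAL_TOL,
    SteadyShearCurve,
    _pvec_of,
    _resid_jac,
    _solve3,
    _steady_reduced,
)
from .params import (
    CCR_STRETCH_EXPONENT,
    FREE_PARAMETERS,
    WATER_VISCOSITY,
    ParamBounds,
    RoliePolyParams,
)

__all__ = [
    "InverseConfig",
    "RestartResult",
    "InverseResult",
    "bounded_map",
    "bounded_map_vector",
    "unbounded_coords",
    "inverse_error",
    "gradient_step",
    "solve_inverse",
    "DirectBackend",
]


def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bounded_map_vector(omega: np.ndarray, bounds: ParamBounds) -> np.ndarray:
    """Sigmoid-bounded map from trial coordinates ω to the parameter vector θ̂."""
    omega = np.asarray(omega, dtype=float)
    return bounds.lower + (bounds.upper - bounds.lower) * _sigmoid(omega)


def bounded_map(
    omega: np.ndarray,
    bounds: ParamBounds,
    eta_s: float = WATER_VISCOSITY,
    delta: float = CCR_STRETCH_EXPONENT,
) -> RoliePolyParams:
    """ω ↦ Θ̂ as a :class:`RoliePolyParams` (strictly inside the bounds)."""
    return RoliePolyParams.from_free_vector(bounded_map_vector(omega, bounds), eta_s=eta_s, delta=delta)


def unbounded_coords(theta: Sequence[float], bounds: ParamBounds) -> np.ndarray:
    """Inverse of the sigmoid map: the ω at which θ̂(ω) equals ``theta``."""
    theta = np.asarray(theta, dtype=float)
    frac = (theta - bounds.lower) / (bounds.upper - bounds.lower)
    if np.any(frac <= 0.0) or np.any(frac >= 1.0):
        raise ValueError("theta must lie strictly inside the bounds")
    return np.log(frac / (1.0 - frac))


# ---------------------------------------------------------------------------
# Prediction backends
# ---------------------------------------------------------------------------

class DirectBackend:
    """Predicts (σxy, N1) with the steady-state Rolie-Poly solver.

    Steady states are cached between calls and reused as warm starts, which
    makes repeated evaluations at nearby parameter vectors cheap.  Parameter
    gradients are exact implicit-function-theorem sensitivities: with
    R(y*, θ) = 0 at the steady reduced state y*, dy*/dθ = −J⁻¹ ∂R/∂θ.
    """

    name = "direct"

    def __init__(
        self,
        rates: np.ndarray,
        eta_s: float = WATER_VISCOSITY,
        delta: float = CCR_STRETCH_EXPONENT,
        tol: float = RESIDUAL_TOL,
        grad_method: Literal["adjoint", "fd"] = "adjoint",
        fd_step: float = 1.0e-6,
    ):
        self.rates = np.asarray(rates, dtype=float)
        self.eta_s = eta_s
        self.delta = delta
        self.tol = tol
        self.grad_method = grad_method
        self.fd_step = fd_step
        self._cache: np.ndarray | None = None

    def _params(self, theta: np.ndarray) -> RoliePolyParams:
        return RoliePolyParams.from_free_vector(theta, eta_s=self.eta_s, delta=self.delta)

    def _solve(self, theta: np.ndarray) -> np.ndarray:
        Y = _steady_reduced(self._params(theta), self.rates, self._cache, self.tol)
        self._cache = Y
        return Y

    def predict(self, theta: np.ndarray) -> np.ndarray:
        """(M, 2) array of (σxy, N1) at the backend's rates."""
        eta_p, tau_D, tau_R, chi, beta = theta
        Y = self._solve(theta)
        return self._stress(theta, Y)

    def _stress(self, theta, Y):
        eta_p, tau_D, tau_R, chi, beta = theta
        ks = self._ks(Y, chi)
        G = eta_p / tau_D
        sigma = self.eta_s * self.rates + G * ks * Y[:, 1]
        N1 = G * ks * (Y[:, 0] - Y[:, 2])
        return np.column_stack([sigma, N1])

    @staticmethod
    def _ks(Y, chi):
        t = Y[:, 0] + 2.0 * Y[:, 2]
        u = t / (3.0 * chi**2)
        w = 1.0 / chi**2
        return ((3.0 - u) * (1.0 - w)) / ((1.0 - u) * (3.0 - w))

    def predict_and_grad(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Stresses (M, 2) and their parameter Jacobian (M, 2, 5)."""
        if self.grad_method == "fd":
            return self.predict(theta), self._grad_fd(theta)
        eta_p, tau_D, tau_R, chi, beta = theta
        Y = self._solve(theta)
        axx, axy, ayy = Y[:, 0], Y[:, 1], Y[:, 2]
        gd = self.rates
        pv = (tau_D, tau_R, chi**2, beta, self.delta)
        _, J, _ = _resid_jac(axx, axy, ayy, gd, *pv)

        # shared scalars of the relaxation term
        t = axx + 2.0 * ayy
        chi2 = chi**2
        w = 1.0 / chi2
        u = t / (3.0 * chi2)
        C = (1.0 - w) / (3.0 - w)
        ks = C * (3.0 - u) / (1.0 - u)
        phi = 1.0 - np.sqrt(3.0 / t)
        psi = (t / 3.0) ** self.delta
        h = (2.0 / tau_R) * ks * phi
        P = np.stack([axx + beta * psi * (axx - 1.0), axy * (1.0 + beta * psi), ayy + beta * psi * (ayy - 1.0)], axis=-1)
        Am_i = np.stack([axx - 1.0, axy, ayy - 1.0], axis=-1)

        # ∂ks/∂χ through w = 1/χ² (C and u both depend on w)
        dC_dw = -2.0 / (3.0 - w) ** 2
        dks_dw = dC_dw * (3.0 - u) / (1.0 - u) + C * (2.0 * t / 3.0) / (1.0 - u) ** 2
        dks_dchi = dks_dw * (-2.0 / chi**3)
        dh_dchi = (2.0 / tau_R) * phi * dks_dchi

        # ∂R/∂θ for the four parameters entering the reduced equations
        dR = np.zeros((gd.size, 3, 5))
        dR[:, :, 1] = Am_i / tau_D**2                      # τD
        dR[:, :, 2] = (h / tau_R)[:, None] * P             # τR
        dR[:, :, 3] = -dh_dchi[:, None] * P                # χmax
        dR[:, :, 4] = -(h * psi)[:, None] * Am_i           # β

        # dy/dθ = −J⁻¹ ∂R/∂θ, column by column
        dY = np.empty((gd.size, 3, 5))
        for k in range(5):
            dY[:, :, k] = _solve3(J, -dR[:, :, k])

        # stress partials: explicit in θ plus chain through y
        G = eta_p / tau_D
        dks_dt = 2.0 * C / ((1.0 - u) ** 2 * 3.0 * chi2)
        dks_dy = np.stack([dks_dt, np.zeros_like(dks_dt), 2.0 * dks_dt], axis=-1)
        n1fac = axx - ayy

        dsig_dy = G * (
            ks[:, None] * np.array([0.0, 1.0, 0.0])[None, :] + axy[:, None] * dks_dy
        )
        dn1_dy = G * (
            ks[:, None] * np.array([1.0, 0.0, -1.0])[None, :] + n1fac[:, None] * dks_dy
        )

        grad = np.empty((gd.size, 2, 5))
        grad[:, 0, :] = np.einsum("mi,mik->mk", dsig_dy, dY)
        grad[:, 1, :] = np.einsum("mi,mik->mk", dn1_dy, dY)
        # explicit parameter dependence of the stress formulas
        grad[:, 0, 0] += ks * axy / tau_D
        grad[:, 1, 0] += ks * n1fac / tau_D
        grad[:, 0, 1] += -G * ks * axy / tau_D
        grad[:, 1, 1] += -G * ks * n1fac / tau_D
        grad[:, 0, 3] += G * dks_dchi * axy
        grad[:, 1, 3] += G * dks_dchi * n1fac
        return self._stress(theta, Y), grad

    def _grad_fd(self, theta: np.ndarray) -> np.ndarray:
        grad = np.empty((self.rates.size, 2, 5))
        for k in range(5):
            hk = self.fd_step * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += hk
            tm[k] -= hk
            grad[:, :, k] = (self.predict(tp) - self.predict(tm)) / (2.0 * hk)
        return grad


def _make_backend(backend, rates, net=None, **kw):
    if isinstance(backend, str):
        if backend == "direct":
            return DirectBackend(rates, **kw)
        if backend == "surrogate":
            if net is None:
                raise ValueError("backend='surrogate' requires a trained net")
            from .surrogate import SurrogateBackend

            return SurrogateBackend(net, rates)
        raise ValueError(f"unknown backend {backend!r}")
    return backend


# ---------------------------------------------------------------------------
# Error functional and descent
# ---------------------------------------------------------------------------

def _check_observations(data: SteadyShearCurve) -> np.ndarray:
    obs = data.stresses()
    if obs.size == 0:
        raise ValueError("input curve is empty")
    if np.any(obs <= 0.0):
        raise ValueError("observed stresses must be strictly positive for the relative error")
    return obs


def inverse_error(
    theta: RoliePolyParams | Sequence[float],
    data: SteadyShearCurve,
    backend: Any = "direct",
    net=None,
) -> float:
    """Mean relative stress misfit Error(Θ) of a trial parameter set.

    Averages |predicted − observed| / observed over the M rate points and
    over the two stress components (σxy, N1); zero iff the prediction
    matches the data exactly.
    """
    obs = _check_observations(data)
    vec = theta.free_vector() if isinstance(theta, RoliePolyParams) else np.asarray(theta, dtype=float)
    be = _make_backend(backend, data.gamma_dot, net=net)
    pred = be.predict(vec)
    return float(np.mean(np.abs(pred - obs) / obs))


def _error_and_grad_omega(omega, obs, bounds, be):
    theta = bounded_map_vector(omega, bounds)
    pred, dpred = be.predict_and_grad(theta)
    resid = pred - obs
    err = float(np.mean(np.abs(resid) / obs))
    dE_dpred = np.sign(resid) / (obs * resid.size)
    dE_dtheta = np.einsum("mc,mck->k", dE_dpred, dpred)
    s = _sigmoid(omega)
    dtheta_domega = (bounds.upper - bounds.lower) * s * (1.0 - s)
    return err, dE_dtheta * dtheta_domega


def gradient_step(
    omega: np.ndarray,
    data: SteadyShearCurve,
    bounds: ParamBounds,
    rho: float,
    backend: Any = "direct",
    net=None,
) -> np.ndarray:
    """One plain gradient-descent update ω ← ω − ρ ∇ω Error(ω)."""
    obs = _check_observations(data)
    be = _make_backend(backend, data.gamma_dot, net=net)
    _, g = _error_and_grad_omega(np.asarray(omega, dtype=float), obs, bounds, be)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError(f"non-finite gradient at omega={omega!r}")
    return np.asarray(omega, dtype=float) - rho * g


# ---------------------------------------------------------------------------
# Multi-restart driver
# ---------------------------------------------------------------------------

@dataclass
class InverseConfig:
    """Tuning of the bounded gradient-descent solver.

    ``rho0`` is the initial step size; it is multiplied by ``rho_decay``
    whenever the best error has improved by less than ``saturation_tol``
    (relative) over the last ``saturation_window`` iterations.  Convergence
    is declared when the ω-update max-norm drops below ``epsilon``.
    """

    rho0: float = 0.2
    rho_decay: float = 0.3
    saturation_window: int = 30
    saturation_tol: float = 1.0e-4
    epsilon: float = 1.0e-6
    max_iters: int = 12000
    #: on ε-convergence the step size and descent moments are reset and the
    #: descent continues (a warm-restart cycle); the run only stops once a
    #: full cycle fails to improve the best error.  This rescues descents
    #: whose step schedule decayed before a weakly-pulled coordinate (e.g.
    #: χmax after a traverse of the under-prediction plateau) reached its
    #: optimum.  ``max_cycles`` bounds the cycling: a parameter sitting
    #: exactly on a bound improves the error a little every cycle, forever.
    cycle_improvement_tol: float = 1.0e-3
    max_cycles: int = 6
    n_restarts: int = 10
    seed: int | None = None
    backend: str = "direct"
    grad_method: Literal["adjoint", "fd"] = "adjoint"
    record_theta: bool = False
    #: first/second-moment averaging constants of the adaptive
    #: (Adam-preconditioned) descent update
    beta1: float = 0.9
    beta2: float = 0.999
    #: |ω| beyond which a coordinate drifting monotonically outward for
    #: ``pin_patience`` iterations is frozen as pinned to its bound
    pin_threshold: float = 8.0
    pin_patience: int = 100
    #: ρ decay is suspended while the best error is above this gate: near
    #: the saturation plateau (relative error ≈ 1, prediction far below the
    #: data) progress per window is tiny and decaying there strands the
    #: descent mid-traverse
    decay_error_gate: float = 0.5

    def __post_init__(self) -> None:
        if self.rho0 <= 0 or not (0.0 < self.rho_decay < 1.0) or self.epsilon <= 0 or self.n_restarts < 1:
            raise ValueError("invalid inverse-solver configuration")


@dataclass
class RestartResult:
    """Outcome of one gradient-descent restart."""

    theta: np.ndarray
    error: float
    n_iters: int
    converged: bool
    error_trajectory: np.ndarray
    unidentified: np.ndarray
    theta_trajectory: np.ndarray | None = None

    @property
    def params(self) -> RoliePolyParams:
        return RoliePolyParams.from_free_vector(self.theta)


@dataclass
class InverseResult:
    """Per-restart recoveries plus mean ± SD aggregates over converged restarts."""

    restarts: list[RestartResult]
    mean: np.ndarray
    sd: np.ndarray
    bounds: ParamBounds
    config: InverseConfig
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def n_converged(self) -> int:
        return sum(r.converged for r in self.restarts)

    @property
    def all_failed(self) -> bool:
        return self.n_converged == 0

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            name: {"mean": float(self.mean[i]), "sd": float(self.sd[i])}
            for i, name in enumerate(FREE_PARAMETERS)
        }


def sample_initial_theta(bounds: ParamBounds, rng: np.random.Generator) -> np.ndarray:
    """One parameter vector uniform over the box on each parameter's scale."""
    out = np.empty(len(FREE_PARAMETERS))
    for i, (_, lo, hi, scale) in enumerate(bounds.items()):
        if scale == "log":
            out[i] = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi))
        else:
            out[i] = rng.uniform(lo, hi)
    return out


def _run_restart(obs, bounds, be, cfg: InverseConfig, omega0: np.ndarray) -> RestartResult:
    """One descent from ``omega0``.

    The update is Adam-preconditioned gradient descent on ω: the raw
    gradient spans many orders of magnitude between the error plateau
    (relative error saturates near 1 wherever the prediction falls far
    below the data) and the basin around the solution, and the
    per-coordinate second-moment scaling makes a single step-size schedule
    work across both.  ρ (the learning rate) decays by ``rho_decay``
    whenever the window-mean error has stopped improving, and iteration
    stops when the update max-norm drops below ε.

    A parameter whose true value sits on a bound drives its ω coordinate
    toward ±∞ at a constant rate without ever satisfying the step
    criterion; such coordinates are detected by their monotone outward
    drift past ``pin_threshold`` and frozen as pinned to the bound.
    """
    omega = np.asarray(omega0, dtype=float).copy()
    rho = cfg.rho0
    m = np.zeros(omega.size)
    v = np.zeros(omega.size)
    errors: list[float] = []
    thetas: list[np.ndarray] = []
    hist: list[float] = []
    best = np.inf
    best_theta = bounded_map_vector(omega, bounds)
    flat_count = np.zeros(omega.size, dtype=int)
    unidentified = np.zeros(omega.size, dtype=bool)
    drift_count = np.zeros(omega.size, dtype=int)
    release_count = np.zeros(omega.size, dtype=int)
    pinned = np.zeros(omega.size, dtype=bool)
    converged = False
    cycle_best = np.inf
    n_cycles = 0
    t_adam = 0
    it = 0
    for it in range(1, cfg.max_iters + 1):
        try:
            err, g = _error_and_grad_omega(omega, obs, bounds, be)
        except FloatingPointError:
            break
        if not (np.isfinite(err) and np.all(np.isfinite(g))):
            break
        errors.append(err)
        if cfg.record_theta:
            thetas.append(bounded_map_vector(omega, bounds))
        if err < best:
            best = err
            best_theta = bounded_map_vector(omega, bounds)
        flat_count = np.where(np.abs(g) < 1.0e-12, flat_count + 1, 0)
        unidentified |= (flat_count >= 100) & ~pinned
        t_adam += 1
        m = cfg.beta1 * m + (1.0 - cfg.beta1) * g
        v = cfg.beta2 * v + (1.0 - cfg.beta2) * g * g
        mhat = m / (1.0 - cfg.beta1**t_adam)
        vhat = v / (1.0 - cfg.beta2**t_adam)
        step = rho * mhat / (np.sqrt(vhat) + 1.0e-12)
        step = np.where(pinned, 0.0, step)
        if np.max(np.abs(step)) < cfg.epsilon:
            n_cycles += 1
            if best >= cycle_best * (1.0 - cfg.cycle_improvement_tol) or n_cycles >= cfg.max_cycles:
                converged = True
                break
            # warm-restart cycle: remember the progress, reset the schedule
            cycle_best = best
            rho = cfg.rho0
            m[:] = 0.0
            v[:] = 0.0
            t_adam = 0
            del hist[:]
            continue
        omega = omega - step
        # pinning is reversible: a pinned coordinate whose gradient starts
        # pulling it back inside the box is released
        inward = pinned & (((omega > 0.0) & (g > 0.0)) | ((omega < 0.0) & (g < 0.0)))
        release_count = np.where(inward, release_count + 1, 0)
        release = release_count >= cfg.pin_patience // 4
        pinned &= ~release
        drift_count = np.where(release, 0, drift_count)
        outward = (omega > cfg.pin_threshold) & (step < 0.0) | (omega < -cfg.pin_threshold) & (step > 0.0)
        drift_count = np.where(
            outward & ~pinned, drift_count + 1, np.maximum(drift_count - 1, 0)
        )
        pinned |= drift_count >= cfg.pin_patience
        # ρ schedule: halve when the mean error over the latest window no
        # longer improves on the window before it
        if best >= cfg.decay_error_gate:
            del hist[:]
        hist.append(err)
        w = cfg.saturation_window
        if len(hist) >= 2 * w:
            prev = float(np.mean(hist[-2 * w : -w]))
            cur = float(np.mean(hist[-w:]))
            if prev - cur < cfg.saturation_tol * prev:
                rho *= cfg.rho_decay
                del hist[:]
    return RestartResult(
        theta=best_theta,
        error=best,
        n_iters=it,
        converged=converged,
        error_trajectory=np.asarray(errors),
        unidentified=unidentified,
        theta_trajectory=np.asarray(thetas) if cfg.record_theta else None,
    )


def solve_inverse(
    data: SteadyShearCurve,
    bounds: ParamBounds,
    config: InverseConfig | None = None,
    net=None,
    eta_s: float = WATER_VISCOSITY,
    delta: float = CCR_STRETCH_EXPONENT,
) -> InverseResult:
    """Recover molecular parameters from a steady shear curve.

    Runs ``config.n_restarts`` independent descents whose starting points
    spread θ̂ uniformly over the bounds on each parameter's sampling scale.
    A restart counts as converged when the update max-norm criterion is met
    within the iteration budget.  If every restart fails the result is
    flagged (``all_failed``) rather than raised.
    """
    cfg = config or InverseConfig()
    obs = _check_observations(data)
    if len(data) < 10:
        import warnings

        warnings.warn(
            "fewer than 10 rate points: molecular parameters may not be identifiable",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    restarts = []
    for _ in range(cfg.n_restarts):
        omega0 = unbounded_coords(sample_initial_theta(bounds, rng), bounds)
        if cfg.backend == "direct":
            be = DirectBackend(data.gamma_dot, eta_s=eta_s, delta=delta, grad_method=cfg.grad_method)
        else:
            be = _make_backend(cfg.backend, data.gamma_dot, net=net)
        restarts.append(_run_restart(obs, bounds, be, cfg, omega0))
    ok = [r.theta for r in restarts if r.converged]
    if ok:
        stack = np.vstack(ok)
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(stack.shape[1])
    else:
        mean = np.full(len(FREE_PARAMETERS), np.nan)
        sd = np.full(len(FREE_PARAMETERS), np.nan)
    return InverseResult(restarts=restarts, mean=mean, sd=sd, bounds=bounds, config=cfg)
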