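"""Scripted validation studies for the inverse solver.

Three seeded, reproducible pipelines:

* noise robustness — perturb the input stresses with bounded multiplicative
  white noise and track how the recovered parameters drift from their
  noise-free solution;
* lambda-DNA validation — regenerate steady curves from reference parameter
  sets for entangled DNA solutions at four concentrations, re-solve them,
  and compare recovered parameters and reconstructed curves;
* convergence benchmarks — error and per-parameter trajectories of the
  descent on randomly sampled truth sets, with data generated either by the
  surrogate itself or by the exact model.

Plus the power-law concentration-scaling fit used on the DNA results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .forward_model import SteadyShearCurve, log_rate_grid, steady_curve
from .inverse import InverseConfig, InverseResult, solve_inverse
from .params import FREE_PARAMETERS, ParamBounds, RoliePolyParams
from .surrogate import SurrogateNet, sample_parameter_array

__all__ = [
    "NoiseSpec",
    "NoiseStudyRow",
    "ScalingFit",
    "add_noise",
    "noise_study",
    "power_law_fit",
    "run_dna_validation",
    "convergence_benchmark",
]


# ---------------------------------------------------------------------------
# Noise robustness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Protocol of the noise-robustness study.

    ``level`` is the maximum fractional deviation of each stress value (the
    noise support is hard-bounded).  ``n_realizations`` independent noisy
    copies of the curve are each solved with ``n_restarts_per_realization``
    random restarts and the recovered parameters pooled.
    """

    n_realizations: int = 8
    n_restarts_per_realization: int = 10
    seed: int | None = None
    distribution: Literal["uniform", "gaussian"] = "uniform"


@dataclass(frozen=True)
class NoiseStudyRow:
    """Pooled estimates at one noise level, normalized by the level-0 mean."""

    level: float
    normalized_mean: np.ndarray
    normalized_sd: np.ndarray
    n_pooled: int


def add_noise(
    curve: SteadyShearCurve,
    level: float,
    seed: int | np.random.Generator | None = None,
    distribution: Literal["uniform", "gaussian"] = "uniform",
) -> SteadyShearCurve:
    """Multiplicative white noise on both stress components.

    Every σxy and N1 value is multiplied by (1 + u) with u i.i.d. uniform on
    [−level, level] (or, optionally, truncated Gaussian with level = 2 SD);
    shear rates are untouched.  ``level=0`` returns the curve unchanged.
    """
    if level < 0:
        raise ValueError("noise level must be nonnegative")
    if level == 0:
        return SteadyShearCurve(
            curve.gamma_dot.copy(), curve.sigma_xy.copy(), curve.N1.copy(), dict(curve.metadata)
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if distribution == "uniform":
        u = rng.uniform(-level, level, size=(curve.gamma_dot.size, 2))
    elif distribution == "gaussian":
        u = rng.normal(0.0, level / 2.0, size=(curve.gamma_dot.size, 2))
        u = np.clip(u, -level, level)
    else:
        raise ValueError(f"unknown noise distribution {distribution!r}")
    return SteadyShearCurve(
        curve.gamma_dot.copy(),
        curve.sigma_xy * (1.0 + u[:, 0]),
        curve.N1 * (1.0 + u[:, 1]),
        {**curve.metadata, "noise_level": level},
    )


def noise_study(
    truth: RoliePolyParams,
    levels: Sequence[float],
    spec: NoiseSpec,
    bounds: ParamBounds,
    inverse_config: InverseConfig,
    rates: np.ndarray | None = None,
    net: SurrogateNet | None = None,
) -> list[NoiseStudyRow]:
    """Parameter-recovery drift under increasing input noise.

    For each level: generate ``n_realizations`` noisy curves, solve each
    with ``n_restarts_per_realization`` restarts, pool all converged
    estimates, and report mean ± SD normalized by the pooled level-0 mean.
    Levels must include 0 (the normalizer); its normalized mean is 1 by
    construction and its SD reflects restart scatter only.
    """
    levels = [float(l) for l in levels]
    if 0.0 not in levels:
        raise ValueError("levels must include 0, the normalizer")
    if rates is None:
        rates = log_rate_grid()
    clean = steady_curve(truth, rates)
    root = np.random.default_rng(spec.seed)
    pooled: dict[float, list[np.ndarray]] = {}
    for level in levels:
        estimates = []
        for _ in range(spec.n_realizations):
            noisy = add_noise(clean, level, root, distribution=spec.distribution)
            cfg = InverseConfig(
                **{
                    **inverse_config.__dict__,
                    "n_restarts": spec.n_restarts_per_realization,
                    "seed": int(root.integers(2**31 - 1)),
                }
            )
            res = solve_inverse(noisy, bounds, cfg, net=net)
            estimates.extend(r.theta for r in res.restarts if r.converged)
        if not estimates:
            raise RuntimeError(
                f"no restart converged at noise level {level}; "
                "increase max_iters or the restart budget"
            )
        pooled[level] = estimates
    base = np.vstack(pooled[0.0]).mean(axis=0)
    rows = []
    for level in levels:
        est = np.vstack(pooled[level]) / base
        rows.append(
            NoiseStudyRow(
                level=level,
                normalized_mean=est.mean(axis=0) if level > 0 else np.ones(base.size),
                normalized_sd=est.std(axis=0, ddof=1),
                n_pooled=est.shape[0],
            )
        )
    return rows


def noise_study_frame(rows: Sequence[NoiseStudyRow]) -> pd.DataFrame:
    """Tidy one-row-per-(level, parameter) table of a noise study."""
    records = []
    for row in rows:
        for i, name in enumerate(FREE_PARAMETERS):
            records.append(
                {
                    "level": row.level,
                    "parameter": name,
                    "normalized_mean": row.normalized_mean[i],
                    "normalized_sd": row.normalized_sd[i],
                    "n_pooled": row.n_pooled,
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Power-law concentration scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingFit:
    """Power law value = prefactor · c^exponent from log-log least squares."""

    exponent: float
    prefactor: float
    r_squared: float
    concentrations: np.ndarray
    values: np.ndarray

    def predict(self, c) -> np.ndarray:
        return self.prefactor * np.asarray(c, dtype=float) ** self.exponent


def power_law_fit(concentrations: Sequence[float], values: Sequence[float]) -> ScalingFit:
    """Ordinary least squares of ln(value) on ln(concentration)."""
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(values, dtype=float)
    if c.size != v.size or c.size < 3:
        raise ValueError("need at least 3 (concentration, value) pairs")
    if np.any(c <= 0) or np.any(v <= 0):
        raise ValueError("concentrations and values must be strictly positive")
    fit = stats.linregress(np.log(c), np.log(v))
    return ScalingFit(
        exponent=float(fit.slope),
        prefactor=float(np.exp(fit.intercept)),
        r_squared=float(fit.rvalue**2),
        concentrations=c,
        values=v,
    )


# ---------------------------------------------------------------------------
# Lambda-DNA validation
# ---------------------------------------------------------------------------

@dataclass
class DnaValidationEntry:
    concentration: float
    extracted: RoliePolyParams
    result: InverseResult
    mean_params: RoliePolyParams
    sigma_rel_err: float
    N1_rel_err: float
    input_curve: SteadyShearCurve
    reconstructed_curve: SteadyShearCurve


@dataclass
class DnaValidationReport:
    entries: list[DnaValidationEntry]
    eta_p_scaling: ScalingFit
    tau_D_scaling: ScalingFit

    def table(self) -> pd.DataFrame:
        """Per-concentration mean ± SD of every parameter plus curve errors."""
        records = []
        for e in self.entries:
            rec = {"concentration": e.concentration}
            for i, name in enumerate(FREE_PARAMETERS):
                rec[f"{name}_extracted"] = getattr(e.extracted, name)
                rec[f"{name}_mean"] = float(e.result.mean[i])
                rec[f"{name}_sd"] = float(e.result.sd[i])
            rec["sigma_rel_err"] = e.sigma_rel_err
            rec["N1_rel_err"] = e.N1_rel_err
            records.append(rec)
        return pd.DataFrame.from_records(records)


def run_dna_validation(
    extracted: Sequence[tuple[float, RoliePolyParams]],
    bounds: ParamBounds,
    inverse_config: InverseConfig,
    rates: np.ndarray | None = None,
    net: SurrogateNet | None = None,
) -> DnaValidationReport:
    """Round-trip validation on the lambda-DNA reference parameter sets.

    For each concentration: generate the steady curve from the extracted
    parameters, solve the inverse problem, recompute the curve from the
    mean recovered parameters, and report the mean relative errors of σxy
    and N1 against the input curve.  Finishes with the ηp and τD power-law
    concentration fits over the recovered means.
    """
    if rates is None:
        rates = log_rate_grid()
    entries = []
    for conc, p in extracted:
        curve = steady_curve(p, rates, metadata={"concentration": conc})
        res = solve_inverse(curve, bounds, inverse_config, net=net, eta_s=p.eta_s, delta=p.delta)
        res.metadata["concentration"] = conc
        mean_p = RoliePolyParams.from_free_vector(res.mean, eta_s=p.eta_s, delta=p.delta)
        recon = steady_curve(mean_p, rates, metadata={"concentration": conc, "source": "recovered"})
        entries.append(
            DnaValidationEntry(
                concentration=conc,
                extracted=p,
                result=res,
                mean_params=mean_p,
                sigma_rel_err=float(np.mean(np.abs(recon.sigma_xy - curve.sigma_xy) / curve.sigma_xy)),
                N1_rel_err=float(np.mean(np.abs(recon.N1 - curve.N1) / curve.N1)),
                input_curve=curve,
                reconstructed_curve=recon,
            )
        )
    concs = [e.concentration for e in entries]
    i_eta, i_tau = FREE_PARAMETERS.index("eta_p"), FREE_PARAMETERS.index("tau_D")
    return DnaValidationReport(
        entries=entries,
        eta_p_scaling=power_law_fit(concs, [float(e.result.mean[i_eta]) for e in entries]),
        tau_D_scaling=power_law_fit(concs, [float(e.result.mean[i_tau]) for e in entries]),
    )


# ---------------------------------------------------------------------------
# Convergence benchmark
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceCase:
    truth: np.ndarray
    error_trajectory: np.ndarray
    param_rel_err_trajectory: np.ndarray  # (iters, 5)
    final_rel_err: np.ndarray
    converged: bool


def convergence_benchmark(
    bounds: ParamBounds,
    inverse_config: InverseConfig,
    n_cases: int = 3,
    data_source: Literal["surrogate", "direct"] = "direct",
    net: SurrogateNet | None = None,
    rates: np.ndarray | None = None,
    seed: int | None = None,
) -> list[ConvergenceCase]:
    """Descent trajectories on randomly sampled truth sets.

    ``data_source`` picks who generates the input stresses: the exact model
    or the surrogate itself.  Inverting surrogate-generated data through
    the surrogate drives the final errors toward zero; inverting exact-model
    data through the surrogate leaves residual parameter errors set by the
    surrogate's stress accuracy (largest for ηp and τD, whose admissible
    ranges span three to four decades).
    """
    if rates is None:
        rates = log_rate_grid()
    if (data_source == "surrogate" or inverse_config.backend == "surrogate") and net is None:
        raise ValueError("a trained net is required for surrogate data or backend")
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n_cases):
        truth = sample_parameter_array(bounds, 1, rng)[0]
        if data_source == "direct":
            curve = steady_curve(RoliePolyParams.from_free_vector(truth), rates)
        else:
            pred = net.predict(truth, rates)
            curve = SteadyShearCurve(rates, pred[:, 0], pred[:, 1])
        cfg = InverseConfig(
            **{
                **inverse_config.__dict__,
                "n_restarts": 1,
                "record_theta": True,
                "seed": int(rng.integers(2**31 - 1)),
            }
        )
        res = solve_inverse(curve, bounds, cfg, net=net)
        r = res.restarts[0]
        rel = np.abs(r.theta_trajectory - truth) / truth
        cases.append(
            ConvergenceCase(
                truth=truth,
                error_trajectory=r.error_trajectory,
                param_rel_err_trajectory=rel,
                final_rel_err=np.abs(r.theta - truth) / truth,
                converged=r.converged,
            )
        )
    return cases
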