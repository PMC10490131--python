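"""Parameter containers for the Rolie-Poly tube model.

A single entangled, monodisperse polymer solution is described by the
molecular parameter set Θ = (ηp, τD, τR, χmax, β) together with two fixed
constants: the solvent viscosity ηs and the convective-constraint-release
(CCR) stretch exponent δ.  The plateau modulus is the derived quantity
G = ηp / τD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

#: Solvent viscosity of water at room temperature [Pa s], the default ηs for
#: aqueous polymer (e.g. DNA) solutions.
WATER_VISCOSITY = 1.0e-3

#: CCR stretch exponent δ of the non-Gaussian Rolie-Poly relaxation term.
#: The conventional single-mode choice is −1/2.
CCR_STRETCH_EXPONENT = -0.5

#: Names of the five free molecular parameters, in canonical vector order.
FREE_PARAMETERS = ("eta_p", "tau_D", "tau_R", "chi_max", "beta")


@dataclass(frozen=True)
class RoliePolyParams:
    """One point Θ in Rolie-Poly molecular-parameter space.

    Parameters
    ----------
    eta_p : float
        Zero-shear polymer viscosity ηp [Pa s].
    tau_D : float
        Reptation (disengagement) time τD [s].
    tau_R : float
        Rouse (stretch) time τR [s].
    chi_max : float
        Maximum chain stretch ratio χmax (dimensionless, > 1).
    beta : float
        Convective-constraint-release coefficient β (dimensionless, ≥ 0).
    eta_s : float
        Solvent viscosity ηs [Pa s]; fixed constant, water by default.
    delta : float
        CCR stretch exponent δ; fixed constant, −1/2 by default.

    Notes
    -----
    τR ≤ τD is *not* enforced: the sampling ranges used for surrogate
    training permit either ordering.
    """

    eta_p: float
    tau_D: float
    tau_R: float
    chi_max: float
    beta: float
    eta_s: float = WATER_VISCOSITY
    delta: float = CCR_STRETCH_EXPONENT

    def __post_init__(self) -> None:
        for name in ("eta_p", "tau_D", "tau_R", "eta_s"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if not self.chi_max > 1.0:
            raise ValueError(f"chi_max must exceed 1, got {self.chi_max!r}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be nonnegative, got {self.beta!r}")

    @property
    def plateau_modulus(self) -> float:
        """Entanglement plateau modulus G = ηp / τD [Pa]."""
        return self.eta_p / self.tau_D

    def free_vector(self) -> np.ndarray:
        """The five free parameters as an array in :data:`FREE_PARAMETERS` order."""
        return np.array([getattr(self, name) for name in FREE_PARAMETERS], dtype=float)

    @classmethod
    def from_free_vector(
        cls,
        theta: Sequence[float],
        eta_s: float = WATER_VISCOSITY,
        delta: float = CCR_STRETCH_EXPONENT,
    ) -> "RoliePolyParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(FREE_PARAMETERS),):
            raise ValueError(f"expected {len(FREE_PARAMETERS)} free parameters, got shape {theta.shape}")
        return cls(*theta, eta_s=eta_s, delta=delta)

    def replace(self, **changes: float) -> "RoliePolyParams":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ParamBounds:
    """Box bounds for the five free parameters, with a per-parameter sampling scale.

    ``scales[i]`` is ``"log"`` (uniform in log10) or ``"linear"`` (uniform);
    it governs both training-set sampling and how inverse-solver restarts are
    spread over the box.
    """

    lower: np.ndarray
    upper: np.ndarray
    scales: tuple[str, ...]

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        n = len(FREE_PARAMETERS)
        if lower.shape != (n,) or upper.shape != (n,) or len(self.scales) != n:
            raise ValueError("bounds must cover exactly the five free parameters")
        if not np.all(lower < upper):
            raise ValueError("each lower bound must be strictly below its upper bound")
        for s in self.scales:
            if s not in ("log", "linear"):
                raise ValueError(f"unknown sampling scale {s!r}")
        if any(s == "log" for s in self.scales) and np.any(lower[self._log_mask()] <= 0):
            raise ValueError("log-scaled parameters need strictly positive lower bounds")

    def _log_mask(self) -> np.ndarray:
        return np.array([s == "log" for s in self.scales])

    @property
    def log_mask(self) -> np.ndarray:
        """Boolean mask of log-scaled parameters, canonical order."""
        return self._log_mask()

    def contains(self, theta: Sequence[float]) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))

    def items(self) -> Iterator[tuple[str, float, float, str]]:
        for i, name in enumerate(FREE_PARAMETERS):
            yield name, float(self.lower[i]), float(self.upper[i]), self.scales[i]

    @classmethod
    def from_mapping(cls, spec: Mapping[str, Mapping[str, object]]) -> "ParamBounds":
        """Build bounds from ``{name: {"min": .., "max": .., "scale": ..}}``."""
        lower, upper, scales = [], [], []
        for name in FREE_PARAMETERS:
            if name not in spec:
                raise KeyError(f"bounds are missing parameter {name!r}")
            entry = spec[name]
            lower.append(float(entry["min"]))  # type: ignore[arg-type]
            upper.append(float(entry["max"]))  # type: ignore[arg-type]
            scales.append(str(entry.get("scale", "linear")))
        return cls(np.array(lower), np.array(upper), tuple(scales))
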