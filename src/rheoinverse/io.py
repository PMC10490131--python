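"""File formats and packaged reference constants.

Curves travel as plain CSV (``shear_rate,sigma_xy,N1``, SI units, ``#``
comments tolerated); inverse results as JSON with a format-version field;
parameter bounds and the lambda-DNA reference parameter sets ship as
packaged YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .forward_model import SteadyShearCurve
from .inverse import InverseResult
from .params import FREE_PARAMETERS, ParamBounds, RoliePolyParams

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "read_result_json",
    "write_result_json",
    "load_bounds",
    "default_bounds",
    "load_lambda_dna_params",
]

RESULT_FORMAT_VERSION = 1


class CurveParseError(ValueError):
    """Malformed curve file; message names the offending line."""


def write_curve_csv(curve: SteadyShearCurve, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key, value in curve.metadata.items():
            fh.write(f"# {key}: {value}\n")
        curve.to_frame().to_csv(fh, index=False)


def read_curve_csv(path) -> SteadyShearCurve:
    path = Path(path)
    metadata: dict[str, Any] = {}
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.readlines()
    data_lines = []
    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if ":" in s:
                key, _, val = s.lstrip("# ").partition(":")
                metadata[key.strip()] = val.strip()
            continue
        data_lines.append((lineno, line))
    if not data_lines:
        raise CurveParseError(f"{path}: no data rows")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(l for _, l in data_lines)))
    required = {"shear_rate", "sigma_xy", "N1"}
    if not required.issubset(df.columns):
        raise CurveParseError(
            f"{path}:{data_lines[0][0]}: header must contain {sorted(required)}, got {list(df.columns)}"
        )
    try:
        return SteadyShearCurve.from_frame(df, metadata=metadata)
    except ValueError as exc:
        raise CurveParseError(f"{path}: {exc}") from exc


def write_result_json(result: InverseResult, path) -> None:
    payload = {
        "format_version": RESULT_FORMAT_VERSION,
        "config": {**asdict(result.config)},
        "bounds": {
            name: {"min": lo, "max": hi, "scale": scale} for name, lo, hi, scale in result.bounds.items()
        },
        "aggregate": {
            "mean": {name: float(result.mean[i]) for i, name in enumerate(FREE_PARAMETERS)},
            "sd": {name: float(result.sd[i]) for i, name in enumerate(FREE_PARAMETERS)},
            "n_converged": result.n_converged,
        },
        "restarts": [
            {
                "theta": {name: float(r.theta[i]) for i, name in enumerate(FREE_PARAMETERS)},
                "error": float(r.error),
                "n_iters": int(r.n_iters),
                "converged": bool(r.converged),
                "unidentified": [FREE_PARAMETERS[i] for i in np.nonzero(r.unidentified)[0]],
            }
            for r in result.restarts
        ],
        "metadata": result.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_result_json(path) -> dict[str, Any]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format_version") != RESULT_FORMAT_VERSION:
        raise ValueError(f"unsupported result format version {payload.get('format_version')!r}")
    return payload


def load_bounds(path) -> ParamBounds:
    """Read parameter bounds from a YAML mapping file."""
    spec = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return ParamBounds.from_mapping(spec)


def _packaged(name: str) -> str:
    return resources.files("rheoinverse.data").joinpath(name).read_text(encoding="utf-8")


def default_bounds() -> ParamBounds:
    """The packaged default parameter box for entangled polymer solutions."""
    return ParamBounds.from_mapping(yaml.safe_load(_packaged("entangled_solution_bounds.yaml")))


def load_lambda_dna_params() -> list[tuple[float, RoliePolyParams]]:
    """The packaged lambda-DNA reference sets as (concentration mg/mL, params)."""
    doc = yaml.safe_load(_packaged("lambda_dna_params.yaml"))
    out = []
    for entry in doc["concentrations"]:
        p = RoliePolyParams(
            eta_p=entry["eta_p"],
            tau_D=entry["tau_D"],
            tau_R=entry["tau_R"],
            chi_max=entry["chi_max"],
            beta=entry["beta"],
        )
        out.append((float(entry["concentration"]), p))
    return out
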