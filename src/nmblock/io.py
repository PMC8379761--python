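"""Configuration files, tabular writers, and deterministic test fixtures.

Configs are flat TOML: top-level keys override the base-case kinetic
parameters (keys are exactly the parameter symbols, e.g. ``k_dissA1``),
an optional ``[solver]`` table sets tolerances and horizon, and an optional
``[run]`` table selects an experiment.  Unknown keys anywhere are rejected,
and every violation is reported at once.

All tabular output is TSV in scientific notation with 12 significant
digits, which makes repeated runs byte-identical without masking
solver-level differences.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .binding import HillFit, hill_curve
from .experiments import InhibitionCurve
from .kinetics import Trajectory
from .parameters import KineticParameters, base_parameters

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "write_trajectory",
    "write_curve",
    "write_hill_fit",
    "write_manifest",
    "fixture_generator",
    "FIXTURE_NAMES",
]

FLOAT_FMT = "%.11e"  # 12 significant digits

_SOLVER_KEYS = {"rtol", "atol", "horizon_ms", "n_points"}
_RUN_KEYS = {"experiment", "drug_M", "output_dir", "verbosity", "label"}
_EXPERIMENTS = (
    "simulate",
    "curve",
    "sweep",
    "ach-response",
    "ic50-shift",
    "fit",
)


class ConfigError(ValueError):
    """Invalid run configuration; message lists every violation."""


@dataclass
class RunConfig:
    """A validated run configuration.

    With no overrides the kinetic parameters reproduce the base case
    exactly.  Times in the config are milliseconds (the natural unit of the
    synaptic event); they are converted to seconds here, at the boundary.
    """

    parameters: KineticParameters = field(default_factory=base_parameters)
    rtol: float = 1e-8
    atol: float = 1e-14
    horizon_s: float = 5e-3
    n_points: int = 2001
    experiment: str = "simulate"
    drug_M: float = 0.0
    output_dir: str = "."
    verbosity: int = 1
    label: str = ""

    def solver_options(self) -> dict[str, Any]:
        return {
            "rtol": self.rtol,
            "atol": self.atol,
            "n_points": self.n_points,
            "horizon": self.horizon_s,
        }


def _config_from_mapping(data: dict[str, Any]) -> RunConfig:
    errors: list[str] = []
    param_keys = set(KineticParameters.field_names())

    solver = data.pop("solver", {}) or {}
    run = data.pop("run", {}) or {}
    if not isinstance(solver, dict):
        errors.append("[solver] must be a table")
        solver = {}
    if not isinstance(run, dict):
        errors.append("[run] must be a table")
        run = {}

    overrides: dict[str, float] = {}
    for key, value in data.items():
        if key not in param_keys:
            errors.append(f"unknown parameter key {key!r}")
        elif not isinstance(value, (int, float)) or isinstance(value, bool):
            errors.append(f"parameter {key!r} must be a number")
        else:
            overrides[key] = float(value)

    for key in solver:
        if key not in _SOLVER_KEYS:
            errors.append(f"unknown [solver] key {key!r}")
    for key in run:
        if key not in _RUN_KEYS:
            errors.append(f"unknown [run] key {key!r}")

    experiment = run.get("experiment", "simulate")
    if experiment not in _EXPERIMENTS:
        errors.append(
            f"unknown experiment {experiment!r}; expected one of "
            f"{_EXPERIMENTS}"
        )

    params: KineticParameters | None = None
    if not errors:
        try:
            params = KineticParameters.from_dict(overrides)
        except (ValueError, KeyError) as exc:
            errors.append(str(exc))

    drug = run.get("drug_M", 0.0)
    if not isinstance(drug, (int, float)) or drug < 0:
        errors.append("run.drug_M must be a number >= 0")

    horizon_ms = solver.get("horizon_ms", 5.0)
    if not isinstance(horizon_ms, (int, float)) or horizon_ms <= 0:
        errors.append("solver.horizon_ms must be a number > 0")

    if errors:
        raise ConfigError(
            "invalid configuration:\n  - " + "\n  - ".join(errors)
        )
    assert params is not None
    return RunConfig(
        parameters=params,
        rtol=float(solver.get("rtol", 1e-8)),
        atol=float(solver.get("atol", 1e-14)),
        horizon_s=float(horizon_ms) * 1e-3,
        n_points=int(solver.get("n_points", 2001)),
        experiment=experiment,
        drug_M=float(drug),
        output_dir=str(run.get("output_dir", ".")),
        verbosity=int(run.get("verbosity", 1)),
        label=str(run.get("label", "")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return _config_from_mapping(data)


def write_parameters(params: KineticParameters, path: str | Path) -> None:
    """Write a parameter set as a flat TOML file (round-trips exactly)."""
    lines = [f"{k} = {v!r}" for k, v in params.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """TSV time course: time_s then the ten states plus derived ORO (M)."""
    _write_tsv(traj.to_frame(), path)


def write_curve(curve: InhibitionCurve, path: str | Path) -> None:
    """TSV inhibition curve plus a JSON sidecar with full provenance."""
    _write_tsv(curve.to_frame(), path)
    sidecar = Path(path).with_suffix(".meta.json")
    meta = {
        "label": curve.label,
        "parameters": curve.parameters.to_dict(),
        "n_drug_values": int(curve.drug_concentrations.size),
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def write_hill_fit(fit: HillFit, path: str | Path) -> None:
    """One-row TSV: IC50_M, n_H, rss, converged."""
    df = pd.DataFrame(
        {
            "IC50_M": [fit.IC50],
            "n_H": [fit.n_H],
            "rss": [fit.residual_sum_of_squares],
            "converged": [fit.converged],
        }
    )
    _write_tsv(df, path)


def write_manifest(
    artifacts: dict[str, str], params: KineticParameters, path: str | Path
) -> None:
    """JSON manifest naming every produced file and the parameter set."""
    payload = {"artifacts": artifacts, "parameters": params.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# fixtures


def _fixture_triangle_peak() -> pd.DataFrame:
    # piecewise-linear trace with a known vertex: 5e-6 M at t = 1 ms
    t = np.linspace(0.0, 2e-3, 41)
    y = 5e-6 * (1.0 - np.abs(t - 1e-3) / 1e-3)
    return pd.DataFrame({"time_s": t, "ARA_star": y})


def _fixture_hill_noiseless() -> pd.DataFrame:
    d = np.concatenate(([0.0], np.logspace(-14, -5, 100)))
    return pd.DataFrame(
        {"drug_M": d, "relative_current": hill_curve(d, 1e-7, 1.2)}
    )


def _fixture_table1() -> pd.DataFrame:
    p = base_parameters()
    return pd.DataFrame(
        {"parameter": list(p.to_dict()), "value": list(p.to_dict().values())}
    )


def _fixture_reference_run() -> pd.DataFrame:
    # drug-free base-case event spec: expected peak times in ms
    return pd.DataFrame(
        {
            "key": ["drug_M", "horizon_ms", "t_peak_ARA_ms", "t_peak_ARA_star_ms"],
            "value": [0.0, 5.0, 0.04, 0.3],
        }
    )


_FIXTURES = {
    "triangle_peak": _fixture_triangle_peak,
    "hill_noiseless": _fixture_hill_noiseless,
    "table1": _fixture_table1,
    "reference_run": _fixture_reference_run,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture_generator(name: str) -> pd.DataFrame:
    """Deterministic bundled inputs for tests and demos.

    Registry: ``triangle_peak`` (synthetic trace with a known vertex),
    ``hill_noiseless`` (exact Hill data, IC50 = 1e-7 M, n_H = 1.2),
    ``table1`` (the base-case parameter set), ``reference_run`` (the
    drug-free event spec with its expected peak times).
    """
    try:
        maker = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {FIXTURE_NAMES}"
        ) from None
    return maker()
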