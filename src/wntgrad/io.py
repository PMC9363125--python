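"""Configuration loading and tabular serialisation.

One configuration dialect (YAML, strictly validated — unknown keys are
errors naming the key), comma-separated text as the sole numeric output
format, and a JSON provenance sidecar from which any output directory can
be regenerated exactly.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .exceptions import ConfigurationError
from .model import ModelParameters, Scenario
from .solver import (
    DEFAULT_ATOL,
    DEFAULT_N_CELLS,
    DEFAULT_N_TIME_SAMPLES,
    DEFAULT_RTOL,
    Grid1D,
    Trajectory,
    discretize_domain,
    simulate,
)

__all__ = [
    "RunConfig",
    "load_config",
    "write_profiles",
    "read_profiles",
    "read_kymograph",
    "run_from_provenance",
]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}
_SCENARIO_FIELDS = {f.name for f in dataclasses.fields(Scenario)}
_GRID_KEYS = {"n_cells"}
_SOLVER_KEYS = {"rtol", "atol", "n_time_samples"}
_OUTPUT_KEYS = {"directory"}
_TOP_KEYS = {"params", "scenario", "grid", "solver", "output", "experiment"}
_EXPERIMENTS = {"feedback_sweep", "robustness", "dnfzd7", "sfrp1_hs"}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration (defaults filled in)."""

    params: ModelParameters = field(default_factory=ModelParameters)
    scenario: Scenario = field(default_factory=Scenario)
    n_cells: int = DEFAULT_N_CELLS
    n_time_samples: int = DEFAULT_N_TIME_SAMPLES
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    output_directory: str | None = None
    experiment: str | None = None

    def grid(self) -> Grid1D:
        return discretize_domain(self.params.x_max, self.n_cells)

    def as_dict(self) -> dict[str, Any]:
        return {
            "params": dataclasses.asdict(self.params),
            "scenario": dataclasses.asdict(self.scenario),
            "grid": {"n_cells": self.n_cells},
            "solver": {"rtol": self.rtol, "atol": self.atol,
                       "n_time_samples": self.n_time_samples},
            "output": {"directory": self.output_directory},
            "experiment": self.experiment,
        }


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigurationError(
            f"unknown key {key!r} in config section {section!r}; "
            f"allowed: {sorted(allowed)}")


def _coerce_number(section: str, key: str, value: Any) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        try:
            return float(value)
        except (TypeError, ValueError):
            raise ConfigurationError(
                f"key {key!r} in section {section!r} must be numeric, got {value!r}"
            ) from None
    return float(value)


def load_config(path: str | Path) -> RunConfig:
    """Parse and strictly validate a YAML run configuration.

    An empty file (or one with empty sections) resolves to the default
    parameter table and wild-type scenario.  Any unrecognised key raises
    :class:`ConfigurationError` naming the key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    _check_keys("<root>", raw, _TOP_KEYS)

    p_over = raw.get("params") or {}
    _check_keys("params", p_over, _PARAM_FIELDS)
    params = ModelParameters(**{k: _coerce_number("params", k, v) for k, v in p_over.items()})

    s_over = raw.get("scenario") or {}
    _check_keys("scenario", s_over, _SCENARIO_FIELDS)
    s_kwargs: dict[str, Any] = {}
    for k, v in s_over.items():
        if k in ("sfrp1_enabled", "hs_enabled"):
            if not isinstance(v, bool):
                raise ConfigurationError(f"key {k!r} in section 'scenario' must be boolean")
            s_kwargs[k] = v
        elif k == "dnfzd7_condition":
            s_kwargs[k] = str(v)
        else:
            s_kwargs[k] = _coerce_number("scenario", k, v)
    scenario = Scenario(**s_kwargs)

    g_over = raw.get("grid") or {}
    _check_keys("grid", g_over, _GRID_KEYS)
    n_cells = int(_coerce_number("grid", "n_cells", g_over.get("n_cells", DEFAULT_N_CELLS)))

    so = raw.get("solver") or {}
    _check_keys("solver", so, _SOLVER_KEYS)
    rtol = _coerce_number("solver", "rtol", so.get("rtol", DEFAULT_RTOL))
    atol = _coerce_number("solver", "atol", so.get("atol", DEFAULT_ATOL))
    n_time_samples = int(_coerce_number(
        "solver", "n_time_samples", so.get("n_time_samples", DEFAULT_N_TIME_SAMPLES)))

    out = raw.get("output") or {}
    _check_keys("output", out, _OUTPUT_KEYS)
    outdir = out.get("directory")

    experiment = raw.get("experiment")
    if experiment is not None and experiment not in _EXPERIMENTS:
        raise ConfigurationError(
            f"unknown experiment {experiment!r}; allowed: {sorted(_EXPERIMENTS)}")

    return RunConfig(params=params, scenario=scenario, n_cells=n_cells,
                     n_time_samples=n_time_samples, rtol=rtol, atol=atol,
                     output_directory=None if outdir is None else str(outdir),
                     experiment=experiment)


def _provenance_dict(traj: Trajectory) -> dict[str, Any]:
    return {
        "package_version": _version,
        "params": dataclasses.asdict(traj.params),
        "scenario": dataclasses.asdict(traj.scenario),
        "grid": {"n_cells": traj.grid.n_cells, "x_max": traj.grid.x_max},
        "solver": {"rtol": traj.diagnostics.get("rtol"),
                   "atol": traj.diagnostics.get("atol"),
                   "n_time_samples": traj.n_times},
        "diagnostics": {k: v for k, v in traj.diagnostics.items()},
    }


def write_profiles(traj: Trajectory, path: str | Path) -> dict[str, Path]:
    """Serialise a trajectory into a directory of text artifacts.

    Writes ``profiles.csv`` (long format: time_s, x_um, species,
    concentration_nM over all 14 components), ``kymograph.csv`` (ω matrix,
    one row per time, header row of cell-centre positions) and
    ``provenance.json`` (everything needed to regenerate the run).
    Numeric formatting is ``repr``-exact, so a read-back reproduces the
    stored values bit-for-bit.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)

    from .model import SPECIES
    n_t, n_s, n_c = traj.states.shape
    long = pd.DataFrame({
        "time_s": np.repeat(traj.times, n_s * n_c),
        "x_um": np.tile(np.repeat([traj.grid.cell_centers], n_s, axis=0).ravel(), n_t),
        "species": np.tile(np.repeat(list(SPECIES), n_c), n_t),
        "concentration_nM": traj.states.ravel(),
    })
    profiles_path = outdir / "profiles.csv"
    long.to_csv(profiles_path, index=False, float_format="%.17g")

    kymo_path = outdir / "kymograph.csv"
    kymo = pd.DataFrame(traj.omega, index=traj.times, columns=traj.grid.cell_centers)
    kymo.index.name = "time_s"
    kymo.to_csv(kymo_path, float_format="%.17g")

    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(_provenance_dict(traj), indent=2, sort_keys=True))
    return {"profiles": profiles_path, "kymograph": kymo_path, "provenance": prov_path}


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Read back a ``profiles.csv`` written by :func:`write_profiles`."""
    return pd.read_csv(Path(path), float_precision="round_trip")


def read_kymograph(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read back a kymograph matrix; returns (times, positions, omega)."""
    df = pd.read_csv(Path(path), index_col=0, float_precision="round_trip")
    return (df.index.to_numpy(dtype=float),
            df.columns.to_numpy(dtype=float),
            df.to_numpy(dtype=float))


def run_from_provenance(path: str | Path) -> Trajectory:
    """Re-run a simulation exactly as recorded in a provenance sidecar."""
    prov = json.loads(Path(path).read_text())
    params = ModelParameters(**prov["params"])
    scenario = Scenario(**prov["scenario"])
    grid = discretize_domain(prov["grid"]["x_max"], prov["grid"]["n_cells"])
    solver = prov["solver"]
    return simulate(scenario, params=params, grid=grid,
                    n_time_samples=int(solver["n_time_samples"]),
                    rtol=float(solver["rtol"]), atol=float(solver["atol"]))
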