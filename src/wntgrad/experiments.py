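"""The model's in-silico experiments as named, reproducible pipelines.

Each runner is a pure function of (parameters, grid, solver settings):
it enumerates scenarios, integrates each one, and condenses trajectories
into tidy metric tables.  The four experiments mirror the questions the
model was built to answer:

* ``run_feedback_sweep`` — does receptor positive feedback steepen the
  signal gradient and narrow the active region?
* ``run_robustness_experiment`` — does feedback (or a high initial
  receptor load) buffer the tissue-boundary position against changes in
  ligand production?
* ``run_dnfzd7_experiment`` — which of the dominant-negative receptor's
  two functions (trapping Wnt vs inactivating Fzd7 by heterodimerisation)
  expands the signalling range?
* ``run_sfrp1_hs_experiment`` — do the antagonist sFRP1 and its HS anchor
  narrow the active region and speed the approach to a steady boundary?
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from . import __version__ as _version
from .exceptions import ConfigurationError, SolverError
from .metrics import (
    active_region_width,
    default_threshold_sweep,
    edge_shift,
    kymograph,
    time_to_steady_edge,
)
from .model import DNFZD7_CONDITIONS, ModelParameters, Scenario
from .solver import (
    DEFAULT_ATOL,
    DEFAULT_N_TIME_SAMPLES,
    DEFAULT_RTOL,
    Grid1D,
    Trajectory,
    discretize_domain,
    simulate,
)

__all__ = [
    "ExperimentResult",
    "run_feedback_sweep",
    "run_robustness_experiment",
    "run_dnfzd7_experiment",
    "run_sfrp1_hs_experiment",
    "DEFAULT_SINGLE_THRESHOLD_FRACTION",
]

#: Single-level metrics (width, time-to-steady) use threshold =
#: fraction × max final ω of the experiment's reference run; a
#: mid-gradient level chosen once (the underlying experiments draw the
#: threshold as an unannotated dashed line).
DEFAULT_SINGLE_THRESHOLD_FRACTION = 0.1


@dataclass(frozen=True)
class ExperimentResult:
    """Trajectories plus condensed metric tables for one experiment."""

    name: str
    runs: tuple[tuple[str, Scenario, Trajectory], ...]
    tables: dict[str, pd.DataFrame]
    arrays: dict[str, NDArray[np.float64]] = dc_field(default_factory=dict)
    provenance: dict[str, Any] = dc_field(default_factory=dict)

    def trajectory(self, scenario_id: str) -> Trajectory:
        for sid, _, traj in self.runs:
            if sid == scenario_id:
                return traj
        raise KeyError(f"no run with scenario id {scenario_id!r}; "
                       f"have {[sid for sid, _, _ in self.runs]}")

    def scenario_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.runs]


def _provenance(name: str, params: ModelParameters, grid: Grid1D,
                **solver_opts: Any) -> dict[str, Any]:
    import dataclasses
    return {
        "experiment": name,
        "package_version": _version,
        "params": dataclasses.asdict(params),
        "grid": {"n_cells": grid.n_cells, "x_max": grid.x_max},
        "solver": dict(solver_opts),
    }


def _run(scenario: Scenario, params: ModelParameters, grid: Grid1D,
         **solver_opts: Any) -> Trajectory:
    try:
        return simulate(scenario, params=params, grid=grid, **solver_opts)
    except SolverError as exc:
        raise SolverError(f"scenario {scenario.label()!r}: {exc}") from exc


def run_feedback_sweep(
    params: ModelParameters | None = None,
    grid: Grid1D | None = None,
    feedback_multipliers: Sequence[float] = (0.0, 1.0, 5.0),
    initial_receptor_multipliers: Sequence[float] = (1.0,),
    *,
    sfrp1_enabled: bool = True,
    hs_enabled: bool = True,
    thresholds: Sequence[float] | None = None,
    n_time_samples: int = DEFAULT_N_TIME_SAMPLES,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> ExperimentResult:
    """Factorial sweep over feedback strength × initial receptor load.

    Defaults run feedback off / normal / strong (0, 1, 5 × p3) at the
    normal initial receptor amount — the contrast behind the claim that
    the signal gradient steepens and the active region narrows as the
    feedback strengthens.

    Tables: ``final_profiles`` (scenario, x, ω at t_max) and ``widths``
    (active-region width per scenario per threshold; thresholds default
    to a log sweep below the largest final ω seen in the sweep).
    """
    if len(feedback_multipliers) == 0 or len(initial_receptor_multipliers) == 0:
        raise ConfigurationError("multiplier lists must be non-empty")
    params = ModelParameters() if params is None else params
    grid = discretize_domain(params.x_max) if grid is None else grid
    opts = dict(n_time_samples=n_time_samples, rtol=rtol, atol=atol)

    runs = []
    for fb in feedback_multipliers:
        for ir in initial_receptor_multipliers:
            sc = Scenario(feedback_multiplier=fb, initial_receptor_multiplier=ir,
                          sfrp1_enabled=sfrp1_enabled, hs_enabled=hs_enabled)
            runs.append((sc.label(), sc, _run(sc, params, grid, **opts)))

    if thresholds is None:
        m = max(float(traj.omega[-1].max()) for _, _, traj in runs)
        thresholds = default_threshold_sweep(m)
    thresholds = np.asarray(thresholds, dtype=float)

    prof_rows, width_rows = [], []
    for sid, sc, traj in runs:
        om = traj.omega[-1]
        prof_rows.append(pd.DataFrame({
            "scenario_id": sid, "feedback": sc.feedback_multiplier,
            "initial_receptor": sc.initial_receptor_multiplier,
            "x_um": grid.cell_centers, "omega_nM": om,
        }))
        width_rows.append(pd.DataFrame({
            "scenario_id": sid, "feedback": sc.feedback_multiplier,
            "initial_receptor": sc.initial_receptor_multiplier,
            "threshold_nM": thresholds,
            "width_um": [active_region_width(om, th, grid) for th in thresholds],
        }))
    tables = {
        "final_profiles": pd.concat(prof_rows, ignore_index=True),
        "widths": pd.concat(width_rows, ignore_index=True),
    }
    return ExperimentResult(
        name="feedback_sweep", runs=tuple(runs), tables=tables,
        provenance=_provenance("feedback_sweep", params, grid, **opts),
    )


def run_robustness_experiment(
    params: ModelParameters | None = None,
    grid: Grid1D | None = None,
    ligand_multipliers: Sequence[float] = (1.0, 1.5),
    feedback_multipliers: Sequence[float] = (0.0, 1.0),
    initial_receptor_multipliers: Sequence[float] = (1.0, 4.0),
    *,
    combos: Sequence[tuple[float, float]] | None = None,
    thresholds: Sequence[float] | None = None,
    n_time_samples: int = DEFAULT_N_TIME_SAMPLES,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> ExperimentResult:
    """Boundary-position robustness against a step in ligand production.

    For each (feedback, initial receptor) combination, the same system is
    run at two Wnt production levels (default 1.0 and 1.5 — a 50%
    increase) and the displacement of the active-region edge is measured
    over a dense threshold sweep.  Small displacements mean the boundary
    is buffered against ligand-production variation.

    ``combos`` restricts the factorial to explicit (feedback, initial)
    pairs.  All combos are evaluated on one shared threshold sweep (up to
    the smallest base-run maximum) so the per-combo statistics compare
    boundary motion at the same absolute signal levels.  Tables:
    ``shifts`` (per combo per threshold, only thresholds crossed by both
    runs of the pair) and ``max_shifts`` (the max-over-thresholds summary
    statistic per combo).
    """
    if len(ligand_multipliers) != 2:
        raise ConfigurationError(
            f"exactly two ligand multipliers required, got {list(ligand_multipliers)!r}")
    params = ModelParameters() if params is None else params
    grid = discretize_domain(params.x_max) if grid is None else grid
    opts = dict(n_time_samples=n_time_samples, rtol=rtol, atol=atol)
    if combos is None:
        if len(feedback_multipliers) == 0 or len(initial_receptor_multipliers) == 0:
            raise ConfigurationError("multiplier lists must be non-empty")
        combos = [(fb, ir) for fb in feedback_multipliers
                  for ir in initial_receptor_multipliers]
    if len(combos) == 0:
        raise ConfigurationError("no (feedback, initial receptor) combinations to run")

    lig_lo, lig_hi = ligand_multipliers
    runs = []
    pairs: list[tuple[float, float, list[Trajectory]]] = []
    for fb, ir in combos:
        pair = []
        for lig in (lig_lo, lig_hi):
            sc = Scenario(feedback_multiplier=fb, initial_receptor_multiplier=ir,
                          ligand_multiplier=lig)
            traj = _run(sc, params, grid, **opts)
            runs.append((sc.label(), sc, traj))
            pair.append(traj)
        pairs.append((fb, ir, pair))

    if thresholds is None:
        common_top = min(float(pair[0].omega[-1].max()) for _, _, pair in pairs)
        thresholds = default_threshold_sweep(common_top)

    shift_rows, max_rows = [], []
    for fb, ir, pair in pairs:
        ths, shifts = edge_shift(pair[0], pair[1], thresholds)
        # restrict the summary to levels actually reached by both runs,
        # where the shift measures boundary motion rather than sentinels
        both = (pair[0].omega[-1].max() >= ths) & (pair[1].omega[-1].max() >= ths)
        shift_rows.append(pd.DataFrame({
            "feedback": fb, "initial_receptor": ir,
            "threshold_nM": ths[both], "shift_um": shifts[both],
        }))
        max_rows.append({
            "feedback": fb, "initial_receptor": ir,
            "max_shift_um": float(shifts[both].max()) if both.any() else np.nan,
            "mean_shift_um": float(shifts[both].mean()) if both.any() else np.nan,
            "n_thresholds": int(both.sum()),
        })
    tables = {
        "shifts": pd.concat(shift_rows, ignore_index=True),
        "max_shifts": pd.DataFrame(max_rows),
    }
    return ExperimentResult(
        name="robustness", runs=tuple(runs), tables=tables,
        provenance=_provenance("robustness", params, grid,
                               ligand_multipliers=list(ligand_multipliers), **opts),
    )


def run_dnfzd7_experiment(
    params: ModelParameters | None = None,
    grid: Grid1D | None = None,
    conditions: Sequence[str] = DNFZD7_CONDITIONS,
    *,
    n_time_samples: int = DEFAULT_N_TIME_SAMPLES,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> ExperimentResult:
    """Dissect the two functions of dominant-negative Fzd7.

    Runs the otherwise-default scenario under each requested condition
    (no dnFzd7 / both functions / inactivate-Fzd7 only / trap-Wnt only)
    and tabulates final ω profiles plus their differences from the
    no-dnFzd7 reference.
    """
    if len(conditions) == 0:
        raise ConfigurationError("conditions must be non-empty")
    unknown = set(conditions) - set(DNFZD7_CONDITIONS)
    if unknown:
        raise ConfigurationError(f"unknown dnFzd7 conditions: {sorted(unknown)}")
    params = ModelParameters() if params is None else params
    grid = discretize_domain(params.x_max) if grid is None else grid
    opts = dict(n_time_samples=n_time_samples, rtol=rtol, atol=atol)

    cond_list = list(dict.fromkeys(conditions))
    if "none" not in cond_list:
        cond_list = ["none"] + cond_list
    runs, prof_rows, diff_rows = [], [], []
    ref_omega = None
    for cond in cond_list:
        sc = Scenario(dnfzd7_condition=cond)
        traj = _run(sc, params, grid, **opts)
        runs.append((cond, sc, traj))
        om = traj.omega[-1]
        if cond == "none":
            ref_omega = om
        prof_rows.append(pd.DataFrame({
            "condition": cond, "x_um": grid.cell_centers, "omega_nM": om}))
        diff_rows.append(pd.DataFrame({
            "condition": cond, "x_um": grid.cell_centers,
            "delta_omega_nM": om - ref_omega}))
    tables = {
        "final_profiles": pd.concat(prof_rows, ignore_index=True),
        "differences_vs_none": pd.concat(diff_rows, ignore_index=True),
    }
    return ExperimentResult(
        name="dnfzd7", runs=tuple(runs), tables=tables,
        provenance=_provenance("dnfzd7", params, grid, conditions=cond_list, **opts),
    )


def run_sfrp1_hs_experiment(
    params: ModelParameters | None = None,
    grid: Grid1D | None = None,
    *,
    include_mixed: bool = False,
    feedback_multiplier: float = 1.0,
    initial_receptor_multiplier: float = 1.0,
    threshold: float | None = None,
    epsilon_um: float = 1.0,
    n_time_samples: int = DEFAULT_N_TIME_SAMPLES,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> ExperimentResult:
    """Contrast the system with and without the sFRP1 + N-acetyl HS module.

    Runs both-on vs both-off (and optionally the two mixed cases, an
    extension beyond the joint contrast) and reports kymographs,
    active-region widths at the reference threshold, and the time for the
    boundary to settle within ``epsilon_um`` of its final position.  The
    reference threshold defaults to
    :data:`DEFAULT_SINGLE_THRESHOLD_FRACTION` × the final maximum ω of
    the both-off run.
    """
    params = ModelParameters() if params is None else params
    grid = discretize_domain(params.x_max) if grid is None else grid
    opts = dict(n_time_samples=n_time_samples, rtol=rtol, atol=atol)

    cases = [("both_on", True, True), ("both_off", False, False)]
    if include_mixed:
        cases += [("sfrp1_only", True, False), ("hs_only", False, True)]

    runs = []
    for cid, sfrp1, hs in cases:
        sc = Scenario(feedback_multiplier=feedback_multiplier,
                      initial_receptor_multiplier=initial_receptor_multiplier,
                      sfrp1_enabled=sfrp1, hs_enabled=hs)
        runs.append((cid, sc, _run(sc, params, grid, **opts)))

    if threshold is None:
        ref = next(traj for cid, _, traj in runs if cid == "both_off")
        threshold = DEFAULT_SINGLE_THRESHOLD_FRACTION * float(ref.omega[-1].max())

    rows, arrays = [], {}
    for cid, sc, traj in runs:
        om = traj.omega[-1]
        steady = time_to_steady_edge(traj, threshold, epsilon_um)
        rows.append({
            "scenario_id": cid, "sfrp1": sc.sfrp1_enabled, "hs": sc.hs_enabled,
            "threshold_nM": threshold,
            "width_um": active_region_width(om, threshold, grid),
            "time_to_steady_s": steady.time,
            "threshold_crossed": steady.threshold_crossed,
            "final_edge_um": steady.final_edge,
        })
        arrays[f"kymograph_{cid}"] = kymograph(traj)
    tables = {"region_metrics": pd.DataFrame(rows)}
    return ExperimentResult(
        name="sfrp1_hs", runs=tuple(runs), tables=tables, arrays=arrays,
        provenance=_provenance("sfrp1_hs", params, grid, threshold=threshold,
                               epsilon_um=epsilon_um, **opts),
    )
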