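"""Derived quantities: the Wnt-signal-active region and its boundary.

A position is "signal-active" at threshold θ when its cumulative activity
ω(x, t) ≥ θ.  With a ligand source at the left edge the ω profile decays
with x, so the active region is an interval [0, edge] and its outer
boundary — the prospective pericardium/myocardium border — is the
rightmost threshold crossing.  Because the drawn threshold level of the
underlying experiments is not a printed number, robustness statements are
evaluated as dense threshold sweeps rather than at any single level.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .exceptions import DomainError, IntegrityError
from .solver import Grid1D, Trajectory

__all__ = [
    "EdgeTrace",
    "SteadyEdgeResult",
    "edge_position",
    "active_region_width",
    "default_threshold_sweep",
    "edge_trace",
    "edge_shift",
    "kymograph",
    "time_to_steady_edge",
]

#: Default number of levels in a threshold sweep; log-spaced over three
#: decades below the profile maximum.  Dense enough that the max-shift
#: statistic is stable to well under a micron.
DEFAULT_N_THRESHOLDS = 200
DEFAULT_SWEEP_DECADES = 3.0

#: Default steadiness tolerance: two cells at the default 0.5 μm resolution.
DEFAULT_EPSILON_UM = 1.0


def edge_position(
    omega_profile: ArrayLike, threshold: float, grid: Grid1D
) -> float:
    """Rightmost position (μm) where ω ≥ threshold.

    Located by linear interpolation between the last cell centre with
    ω ≥ θ and its right neighbour.  Sentinels: 0 when the profile is
    everywhere below threshold, x_max when the last cell is still above.
    """
    if not threshold > 0:
        raise DomainError(f"threshold must be > 0, got {threshold!r}")
    om = np.asarray(omega_profile, dtype=float)
    if om.shape != (grid.n_cells,):
        raise IntegrityError(
            f"profile length {om.shape} does not match grid ({grid.n_cells} cells)")
    above = np.nonzero(om >= threshold)[0]
    if above.size == 0:
        return 0.0
    i = int(above[-1])
    if i == grid.n_cells - 1:
        return grid.x_max
    x = grid.cell_centers
    # om[i] >= threshold > om[i+1] by construction of i
    frac = (om[i] - threshold) / (om[i] - om[i + 1])
    return float(x[i] + frac * (x[i + 1] - x[i]))


def active_region_width(
    omega_profile: ArrayLike, threshold: float, grid: Grid1D
) -> float:
    """Total measure (μm) of {x : ω(x) ≥ threshold}.

    The profile is taken piecewise-linear between cell centres and constant
    from the domain edges to the outermost centres.  For the usual profiles
    that decrease monotonically from the source this equals
    :func:`edge_position`; for non-monotone profiles (e.g. under dnFzd7)
    it is the summed length of every super-threshold interval.
    """
    if not threshold > 0:
        raise DomainError(f"threshold must be > 0, got {threshold!r}")
    om = np.asarray(omega_profile, dtype=float)
    if om.shape != (grid.n_cells,):
        raise IntegrityError(
            f"profile length {om.shape} does not match grid ({grid.n_cells} cells)")
    x = grid.cell_centers
    # extend with constant values to the physical boundaries
    xs = np.concatenate([[0.0], x, [grid.x_max]])
    ys = np.concatenate([[om[0]], om, [om[-1]]])
    above = ys >= threshold
    width = 0.0
    for k in range(xs.size - 1):
        x0, x1, y0, y1 = xs[k], xs[k + 1], ys[k], ys[k + 1]
        if above[k] and above[k + 1]:
            width += x1 - x0
        elif above[k] != above[k + 1] and y0 != y1:
            xc = x0 + (threshold - y0) / (y1 - y0) * (x1 - x0)
            width += (xc - x0) if above[k] else (x1 - xc)
    return float(width)


def default_threshold_sweep(
    max_omega: float,
    n_levels: int = DEFAULT_N_THRESHOLDS,
    decades: float = DEFAULT_SWEEP_DECADES,
) -> NDArray[np.float64]:
    """Log-spaced threshold levels spanning ``decades`` below ``max_omega``."""
    if not max_omega > 0:
        raise DomainError("max_omega must be > 0 to define a threshold sweep")
    return np.logspace(np.log10(max_omega) - decades, np.log10(max_omega), n_levels)


@dataclass(frozen=True)
class EdgeTrace:
    """Edge position as a function of threshold and time.

    ``edge_positions[i, j]`` is the boundary of the active region at
    ``thresholds[i]`` and ``times[j]`` (μm, sentinels 0 / x_max included);
    ``crossed[i, j]`` is False where the profile never reached the
    threshold (edge reported as the 0 sentinel).
    """

    thresholds: NDArray[np.float64]
    times: NDArray[np.float64]
    edge_positions: NDArray[np.float64]
    crossed: NDArray[np.bool_]


def edge_trace(traj: Trajectory, thresholds: ArrayLike) -> EdgeTrace:
    """Track the active-region boundary over all saved times for each level."""
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    om = traj.omega
    edges = np.empty((thresholds.size, traj.n_times))
    crossed = np.empty((thresholds.size, traj.n_times), dtype=bool)
    for i, th in enumerate(thresholds):
        for j in range(traj.n_times):
            edges[i, j] = edge_position(om[j], th, traj.grid)
            crossed[i, j] = bool(np.any(om[j] >= th))
    return EdgeTrace(thresholds=thresholds, times=traj.times.copy(),
                     edge_positions=edges, crossed=crossed)


def edge_shift(
    traj_base: Trajectory,
    traj_perturbed: Trajectory,
    thresholds: ArrayLike | None = None,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """|edge(perturbed) − edge(base)| at final time, per threshold (μm).

    Measures positional robustness: how far the tissue boundary moves when
    production is perturbed, across the whole range of plausible threshold
    levels.  Default sweep: log-spaced levels spanning three decades up to
    the base run's final-profile maximum.  The shift itself is symmetric
    in the two trajectories; pass explicit ``thresholds`` for a sweep that
    does not privilege the base run.

    Returns ``(thresholds, shifts)``.
    """
    if traj_base.grid != traj_perturbed.grid and (
        traj_base.grid.n_cells != traj_perturbed.grid.n_cells
        or traj_base.grid.x_max != traj_perturbed.grid.x_max
    ):
        raise IntegrityError("trajectories use different grids")
    if traj_base.times.shape != traj_perturbed.times.shape or not np.allclose(
        traj_base.times, traj_perturbed.times
    ):
        raise IntegrityError("trajectories use different time samples")
    if thresholds is None:
        thresholds = default_threshold_sweep(float(traj_base.omega[-1].max()))
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    ob, op = traj_base.omega[-1], traj_perturbed.omega[-1]
    shifts = np.array([
        abs(edge_position(op, th, traj_perturbed.grid)
            - edge_position(ob, th, traj_base.grid))
        for th in thresholds
    ])
    return thresholds, shifts


def kymograph(traj: Trajectory) -> NDArray[np.float64]:
    """ω as a (n_times, n_cells) matrix, rows top-to-bottom in time.

    The standard space-time heatmap: each saved profile becomes one row, so
    a threshold contour that runs vertically means the boundary position
    has stopped moving.
    """
    if traj.n_times < 2:
        raise IntegrityError("kymograph needs at least 2 time samples")
    return traj.omega.copy()


class SteadyEdgeResult(NamedTuple):
    """Earliest time after which the boundary stays put, plus context."""

    time: float                 #: earliest sampled t₀ with |edge(t)−edge(t_max)| ≤ ε ∀ t ≥ t₀
    threshold_crossed: bool     #: False if ω never reaches the threshold by t_max
    final_edge: float           #: edge position at t_max (μm)


def time_to_steady_edge(
    traj: Trajectory, threshold: float, epsilon: float = DEFAULT_EPSILON_UM
) -> SteadyEdgeResult:
    """How quickly the active-region boundary settles ("contour verticality").

    Returns the earliest sampled time t₀ such that the edge stays within
    ``epsilon`` μm of its final position from t₀ onwards.  If the threshold
    is never crossed at t_max the result carries ``threshold_crossed=False``
    and the latest sample time.
    """
    if not epsilon > 0:
        raise DomainError(f"epsilon must be > 0, got {epsilon!r}")
    trace = edge_trace(traj, [threshold])
    edges = trace.edge_positions[0]
    if not trace.crossed[0, -1]:
        return SteadyEdgeResult(time=float(traj.times[-1]),
                                threshold_crossed=False, final_edge=float(edges[-1]))
    ok = np.abs(edges - edges[-1]) <= epsilon
    bad = np.nonzero(~ok)[0]
    idx = 0 if bad.size == 0 else int(bad[-1]) + 1
    return SteadyEdgeResult(time=float(traj.times[idx]),
                            threshold_crossed=True, final_edge=float(edges[-1]))
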