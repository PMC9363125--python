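"""Desk-scale fixtures and independent reference computations.

The fixtures are deterministic, reduced-size configurations of the tissue
model (shortened horizons, coarse grids, optionally softened HS density)
that finish in seconds.  :func:`explicit_reference_simulate` integrates
the very same equations with a deliberately naive fixed-step forward-Euler
scheme written without touching the production solver's integration code;
agreement between the two on softened fixtures, together with the
closed-form conservation laws in :func:`mass_balance_report`, is the
package's core correctness gate.

The physiological HS density (1e8 nM) makes the sFRP1–HS binding relax at
~1.9e4 s⁻¹; explicit integration at that stiffness over long horizons is
infeasible, so oracle fixtures soften h0_amp to 1e3 nM and validation of
the full-stiffness regime relies on the conservation laws and on
tolerance/grid refinement instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from . import model
from .exceptions import ConfigurationError
from .model import (
    N_SPECIES,
    SPECIES_INDEX,
    ModelParameters,
    Scenario,
    effective_parameters,
)
from .solver import Grid1D, Trajectory, discretize_domain, initial_state

__all__ = [
    "Fixture",
    "make_fixture_scenarios",
    "fixture_grid",
    "fixture_initial_state",
    "explicit_reference_simulate",
    "mass_balance_report",
    "stability_rate_bound",
]


@dataclass(frozen=True)
class Fixture:
    """One named, deterministic reduced-scale model configuration."""

    name: str
    params: ModelParameters
    scenario: Scenario
    n_cells: int
    n_time_samples: int = 51
    #: uniform concentrations (nM) added to the standard R₀/H₀ initial
    #: state, e.g. {"W": 10, "S": 10} for the closed binding fixture
    uniform_initial: dict[str, float] = field(default_factory=dict)
    #: True when the fixture is soft enough for the explicit oracle
    oracle_compatible: bool = False
    description: str = ""


def make_fixture_scenarios() -> list[Fixture]:
    """The standard fixture battery (each completes in well under a minute).

    * ``no_ligand`` — Wnt production off: every Wnt-containing species and
      ω must stay identically zero and the receptor profile frozen.
    * ``no_antagonist`` — sFRP1 and HS both absent: the S/H sector of the
      state must remain empty.
    * ``closed_binding`` — well-mixed closed W+S system (no productions, no
      receptor, no HS): relaxes to the binding equilibrium
      [WS]/([W][S]) = k2/k2_off.
    * ``stiff_hs`` — short-horizon run at the full 1e8 nM HS density,
      exercising the stiff regime for the conservation checks.
    * ``default_miniature`` — the wild-type scenario at 1/10 the duration
      on a 50-cell grid; the conservation-suite workhorse.
    * ``oracle_soft`` — default scenario with HS softened to 1e3 nM on a
      25-cell grid over 1e3 s; directly comparable to the explicit oracle.
    """
    base = ModelParameters()
    mini = base.replace(t_max=1e4)
    soft = base.replace(t_max=1e3, h0_amp=1e3)
    return [
        Fixture(
            name="no_ligand", params=mini, n_cells=50,
            scenario=Scenario(ligand_multiplier=0.0),
            description="no Wnt source: signal sector must stay empty",
        ),
        Fixture(
            name="no_antagonist", params=mini, n_cells=50,
            scenario=Scenario(sfrp1_enabled=False, hs_enabled=False),
            description="no sFRP1/HS: antagonist sector must stay empty",
        ),
        Fixture(
            name="closed_binding",
            params=mini.replace(h0_amp=0.0),
            scenario=Scenario(ligand_multiplier=0.0, sfrp1_enabled=False,
                              hs_enabled=False, initial_receptor_multiplier=0.0),
            n_cells=20,
            uniform_initial={"W": 10.0, "S": 10.0},
            oracle_compatible=True,
            description="closed well-mixed W+S binding, relaxes to k2/k2_off",
        ),
        Fixture(
            name="stiff_hs", params=base.replace(t_max=2e3), n_cells=25,
            scenario=Scenario(),
            description="full 1e8 nM HS density over a short horizon",
        ),
        Fixture(
            name="default_miniature", params=mini, n_cells=50,
            scenario=Scenario(),
            description="wild-type scenario, 1/10 duration, 2 um cells",
        ),
        Fixture(
            name="oracle_soft", params=soft, n_cells=25,
            scenario=Scenario(), oracle_compatible=True,
            description="softened HS (1e3 nM), 1e3 s, explicit-oracle comparable",
        ),
    ]


def fixture_grid(fixture: Fixture) -> Grid1D:
    return discretize_domain(fixture.params.x_max, fixture.n_cells)


def fixture_initial_state(fixture: Fixture, grid: Grid1D | None = None) -> NDArray[np.float64]:
    """Standard R₀/H₀ initial state plus the fixture's uniform additions."""
    grid = fixture_grid(fixture) if grid is None else grid
    c0 = initial_state(fixture.params, fixture.scenario, grid)
    for name, value in fixture.uniform_initial.items():
        c0[SPECIES_INDEX[name]] += float(value)
    return c0


def stability_rate_bound(fixture: Fixture, grid: Grid1D) -> float:
    """Crude upper bound (s⁻¹) on the fastest linearised rate of a fixture.

    Used to guard the explicit oracle: forward Euler needs
    dt · bound < 0.1.  Sums the fastest unimolecular rates, bimolecular
    rates at the largest initial concentrations, and the diffusion CFL
    rate 4·D/Δx².
    """
    p = effective_parameters(fixture.params, fixture.scenario)
    c0 = fixture_initial_state(fixture, grid)
    h_max = float(c0[SPECIES_INDEX["H"]].max())
    r_max = float(c0[SPECIES_INDEX["R"]].max())
    c_max = float(c0.max())
    return (
        p.k3 * h_max + p.k3_off + p.k2_off + p.k1_off + p.k4
        + p.k1 * max(r_max, c_max) ** 2
        + p.k2 * c_max
        + 4.0 * p.diff_coef / grid.cell_width**2
    )


def explicit_reference_simulate(fixture: Fixture, dt: float) -> Trajectory:
    """Fixed-step forward-Euler reference integration of a fixture.

    A deliberately simple transcription of the same reaction terms and
    3-point zero-flux diffusion stencil, sharing no integration machinery
    with :func:`wntgrad.solver.simulate`.  Only usable on fixtures soft
    enough for explicit stability (guarded by dt · rate bound < 0.1).

    ``dt`` is rounded down so that a whole number of steps lands exactly
    on each output sample time.
    """
    grid = fixture_grid(fixture)
    bound = stability_rate_bound(fixture, grid)
    if dt * bound >= 0.1:
        raise ConfigurationError(
            f"dt={dt:g} s too large for explicit stability: dt*rate_bound = "
            f"{dt * bound:.3g} >= 0.1 (rate bound {bound:.3g}/s)")

    p = effective_parameters(fixture.params, fixture.scenario)
    f = model.wnt_production_profile(grid.cell_centers, p)
    g = model.sfrp1_production_profile(grid.cell_centers, p)
    t_eval = np.linspace(0.0, p.t_max, fixture.n_time_samples)
    interval = t_eval[1] - t_eval[0]
    steps_per_interval = int(np.ceil(interval / dt))
    h = interval / steps_per_interval

    idx_w, idx_s, idx_ws = (SPECIES_INDEX[s] for s in ("W", "S", "WS"))
    inv_dx2 = p.diff_coef / grid.cell_width**2
    c = fixture_initial_state(fixture, grid)
    saved = np.empty((fixture.n_time_samples, N_SPECIES, grid.n_cells))
    saved[0] = c
    for j in range(1, fixture.n_time_samples):
        for _ in range(steps_per_interval):
            dc = model._mass_action_rhs(c, f, g, p)
            for a in (idx_w, idx_s, idx_ws):
                row = c[a]
                left = np.concatenate([row[:1], row[:-1]])
                right = np.concatenate([row[1:], row[-1:]])
                dc[a] += inv_dx2 * (left - 2.0 * row + right)
            c = c + h * dc
        saved[j] = c
    saved = np.clip(saved, 0.0, None)
    return Trajectory(
        grid=grid, times=t_eval, states=saved,
        params=fixture.params, scenario=fixture.scenario,
        diagnostics={"method": "forward-euler-reference", "dt": h,
                     "steps_per_interval": steps_per_interval},
    )


# ---------------------------------------------------------------------------
# conservation accounting

_WNT_MOIETY = ("W", "WS", "WSH", "WR2", "WD2", "WRD")
_HS_MOIETY = ("H", "SH", "WSH")
_SFRP1_MOIETY = ("S", "WS", "SH", "WSH")


def _total(traj: Trajectory, names: tuple[str, ...],
           weights: tuple[float, ...] | None = None) -> NDArray[np.float64]:
    w = weights or (1.0,) * len(names)
    acc = np.zeros(traj.n_times)
    for name, wt in zip(names, w):
        acc += wt * traj.species(name).sum(axis=1)
    return acc * traj.grid.cell_width


def mass_balance_report(traj: Trajectory) -> pd.DataFrame:
    """Per-time conserved-moiety totals vs their closed-form expectations.

    Columns (totals are spatial integrals in nM·μm):

    * Wnt: every Wnt-containing species plus ω must equal the initial
      total plus the production integral p1·|source|·t — internalisation
      moves ligand into ω one-for-one.
    * HS: no production, degradation or transport, so the per-cell total
      H+SH+WSH is frozen; both the global total and the worst per-cell
      relative drift are reported.
    * Fzd7: each internalisation event consumes two receptors and feeds
      back p3 new ones, so the receptor moiety equals its initial total
      plus (p3 − 2)·∫ω dx.
    * dnFzd7: produced at p4 per internalisation, never removed.
    * sFRP1: produced (Hill-gated), never removed — total must be
      non-decreasing; no closed form because the gate depends on ω(x,t).

    Relative errors use the largest magnitude of the expected series as
    denominator (so identically-zero sectors report zero error).
    """
    p = effective_parameters(traj.params, traj.scenario)
    dx = traj.grid.cell_width
    t = traj.times
    f = model.wnt_production_profile(traj.grid.cell_centers, p)
    source_len = float(f.sum() * dx)

    omega_int = traj.omega.sum(axis=1) * dx

    wnt = _total(traj, _WNT_MOIETY) + omega_int
    wnt_expected = wnt[0] + p.p1 * source_len * t

    hs = _total(traj, _HS_MOIETY)
    hs_expected = np.full_like(t, hs[0])
    hs_cells = sum(traj.species(s) for s in _HS_MOIETY)
    h0 = hs_cells[0]
    occupied = h0 > 0
    if np.any(occupied):
        hs_cell_err = np.abs(hs_cells[:, occupied] / h0[occupied] - 1.0).max(axis=1)
    else:
        hs_cell_err = np.abs(hs_cells).max(axis=1) if hs_cells.size else np.zeros_like(t)

    fzd7 = _total(traj, ("R", "WR2", "RD", "WRD"), (1.0, 2.0, 1.0, 1.0))
    fzd7_expected = fzd7[0] + (p.p3 - 2.0) * (omega_int - omega_int[0])

    dn = _total(traj, ("Dn", "RD", "D2", "WD2", "WRD"), (1.0, 1.0, 2.0, 2.0, 1.0))
    dn_expected = dn[0] + p.p4 * (omega_int - omega_int[0])

    sfrp1 = _total(traj, _SFRP1_MOIETY)

    def rel(err_num: NDArray, expected: NDArray) -> NDArray:
        scale = float(np.abs(expected).max())
        if scale == 0.0:
            scale = 1.0
        return np.abs(err_num) / scale

    return pd.DataFrame({
        "time_s": t,
        "wnt_total": wnt, "wnt_expected": wnt_expected,
        "wnt_rel_err": rel(wnt - wnt_expected, wnt_expected),
        "hs_total": hs, "hs_expected": hs_expected,
        "hs_rel_err": rel(hs - hs_expected, hs_expected),
        "hs_max_cell_rel_err": hs_cell_err,
        "fzd7_total": fzd7, "fzd7_expected": fzd7_expected,
        "fzd7_rel_err": rel(fzd7 - fzd7_expected, fzd7_expected),
        "dnfzd7_total": dn, "dnfzd7_expected": dn_expected,
        "dnfzd7_rel_err": rel(dn - dn_expected, dn_expected),
        "sfrp1_total": sfrp1,
    })
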