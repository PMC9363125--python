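"""Reaction network of extracellular Wnt6 regulation in cardiogenic mesoderm.

The model tracks thirteen molecular species on a 1-D strip of tissue (the
lateral half of the prospective heart field, x = 0..x_max μm) plus the
cumulative Wnt signalling activity ω:

=====  ==========================================================
W      free Wnt6 ligand (diffusible)
S      free sFRP1 antagonist (diffusible)
WS     Wnt6·sFRP1 complex (diffusible)
H      free N-acetyl-rich heparan sulfate binding sites (immobile)
SH     sFRP1 bound to HS
WSH    Wnt6·sFRP1 bound to HS
R      free Fzd7 receptor
WR2    signalling complex: one Wnt6 bound by two Fzd7
Dn     free dominant-negative Fzd7 (lacks the intracellular domain)
RD     Fzd7·dnFzd7 heterodimer (signalling-dead)
D2     dnFzd7 homodimer
WD2    Wnt6 trapped on a dnFzd7 homodimer
WRD    Wnt6 trapped on a Fzd7·dnFzd7 heterodimer
omega  ω = k4·∫[WR2] dt, cumulative internalisation flux — the
       proxy for pathway activation at each position
=====  ==========================================================

Two Fzd7 molecules bind one Wnt6; the WR2 complex is internalised at rate
k4, which both destroys the ligand and drives two feedback productions:
new receptor at rate p3·k4·[WR2] (the receptor positive feedback) and, in
dominant-negative experiments, dnFzd7 at rate p4·k4·[WR2].  sFRP1
production is repressed by the local signal through a Hill term and
restricted to the prospective-myocardium side of the field; Wnt6
production is restricted to the epidermal source at the left edge.

Everything here is a pure function of state and parameters; space-time
integration lives in :mod:`wntgrad.solver`.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .exceptions import ConfigurationError, DomainError, IntegrityError

__all__ = [
    "SPECIES",
    "DIFFUSIVE_SPECIES",
    "ModelParameters",
    "Scenario",
    "StateField",
    "NondimensionalScaling",
    "DnFzd7Params",
    "DNFZD7_CONDITIONS",
    "wnt_production_profile",
    "sfrp1_production_profile",
    "initial_receptor_profile",
    "initial_hs_profile",
    "hill_repression",
    "dnfzd7_condition_params",
    "effective_parameters",
    "reaction_rhs",
    "nondimensionalize",
    "redimensionalize",
]

#: Fixed species ordering used everywhere a state block is flattened.
SPECIES: tuple[str, ...] = (
    "W", "S", "WS", "H", "SH", "WSH", "R",
    "WR2", "Dn", "RD", "D2", "WD2", "WRD", "omega",
)
N_SPECIES = len(SPECIES)
SPECIES_INDEX: dict[str, int] = {n: i for i, n in enumerate(SPECIES)}

#: Species carrying a diffusion term (free ligand, free antagonist, their
#: complex); everything else is membrane-anchored or HS-bound and immobile.
DIFFUSIVE_SPECIES: tuple[str, ...] = ("W", "S", "WS")
DIFFUSIVE_INDICES: tuple[int, ...] = tuple(SPECIES_INDEX[s] for s in DIFFUSIVE_SPECIES)

_IW, _IS, _IWS, _IH, _ISH, _IWSH, _IR, _IWR2, _IDN, _IRD, _ID2, _IWD2, _IWRD, _IOM = range(14)


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, production rates and geometry of the tissue model.

    Units: concentrations nM, lengths μm, times s.  Defaults are the
    wild-type parameterisation of Xenopus heart-field patterning.
    """

    k1: float = 2.66e-6       #: Wnt6 + 2 Fzd7 association, nM⁻² s⁻¹
    k1_off: float = 9.6e-5    #: shared dissociation rate of receptor complexes, s⁻¹
    k2: float = 4.33e-5       #: Wnt6 + sFRP1 (free or HS-bound) association, nM⁻¹ s⁻¹
    k2_off: float = 4.86e-4   #: Wnt6·sFRP1 dissociation, s⁻¹
    k3: float = 1.86e-4       #: sFRP1 (free or Wnt-bound) + HS association, nM⁻¹ s⁻¹
    k3_off: float = 3.66e-3   #: sFRP1·HS dissociation, s⁻¹
    k4: float = 2.52e-4       #: internalisation of the WR2 signalling complex, s⁻¹
    k5: float = 2.66e-6       #: Wnt6 + 2 dnFzd7 association, nM⁻² s⁻¹
    k6: float = 2.66e-6       #: Wnt6 + Fzd7 + dnFzd7 association, nM⁻² s⁻¹
    k7: float = 0.0           #: Wnt-catalysed R+Dn / Dn+Dn dimerisation, nM⁻² s⁻¹
    p1: float = 1e-4          #: Wnt6 production rate density in the source, nM s⁻¹
    p2: float = 1e-3          #: sFRP1 production rate density in the source, nM s⁻¹
    p3: float = 10.0          #: receptor production per internalisation event (feedback gain)
    p4: float = 0.0           #: dnFzd7 production per internalisation event
    Kd: float = 1e-2          #: Hill constant of sFRP1 repression by ω, nM
    hill_n: float = 2.0       #: Hill coefficient of that repression
    diff_coef: float = 20.0   #: diffusion coefficient of W, S, WS, μm² s⁻¹
    r0: float = 75.0          #: amplitude of the initial Fzd7 bump, nM
    h0_amp: float = 1e8       #: amplitude of the N-acetyl HS profile, nM
    x_max: float = 100.0      #: width of the developmental field, μm
    t_max: float = 1e5        #: simulated duration (≈ 1 day of heart development), s
    wnt_source_right_edge: float = 10.0   #: Wnt6 produced for x ≤ this, μm
    sfrp1_source_left_edge: float = 25.0  #: sFRP1 produced for x ≥ this, μm
    bump_left: float = 10.0   #: left end of the R₀ / H₀ sinusoidal bump, μm
    bump_right: float = 40.0  #: right end of the R₀ / H₀ sinusoidal bump, μm

    def __post_init__(self) -> None:
        for name in ("k1", "k1_off", "k2", "k2_off", "k3", "k3_off", "k4",
                     "k5", "k6", "k7", "p1", "p2", "p3", "p4", "Kd",
                     "diff_coef", "r0", "h0_amp", "wnt_source_right_edge",
                     "sfrp1_source_left_edge", "bump_left", "bump_right"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v!r}")
        if self.hill_n < 1:
            raise ConfigurationError(f"hill_n must be >= 1, got {self.hill_n!r}")
        if not self.x_max > 0:
            raise ConfigurationError(f"x_max must be > 0, got {self.x_max!r}")
        if not self.t_max > 0:
            raise ConfigurationError(f"t_max must be > 0, got {self.t_max!r}")
        if not (self.wnt_source_right_edge < self.sfrp1_source_left_edge < self.x_max):
            raise ConfigurationError(
                "need wnt_source_right_edge < sfrp1_source_left_edge < x_max, got "
                f"{self.wnt_source_right_edge}, {self.sfrp1_source_left_edge}, {self.x_max}")
        if not (self.bump_left < self.bump_right <= self.x_max):
            raise ConfigurationError(
                f"need bump_left < bump_right <= x_max, got "
                f"{self.bump_left}, {self.bump_right}, {self.x_max}")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


#: Valid dominant-negative Fzd7 experimental conditions.
DNFZD7_CONDITIONS: tuple[str, ...] = ("none", "both_functions", "inactivate_only", "trap_only")


@dataclass(frozen=True)
class Scenario:
    """Experiment switchboard applied on top of :class:`ModelParameters`.

    Each switch is a parameter override, never a structural change to the
    equations: feedback_multiplier scales p3, initial_receptor_multiplier
    scales r0, ligand_multiplier scales p1, disabling sFRP1 zeroes p2,
    disabling HS zeroes h0_amp, and the dnFzd7 condition selects one row of
    the (p4, k5, k6, k7) condition table.
    """

    feedback_multiplier: float = 1.0
    initial_receptor_multiplier: float = 1.0
    ligand_multiplier: float = 1.0
    sfrp1_enabled: bool = True
    hs_enabled: bool = True
    dnfzd7_condition: str = "none"

    def __post_init__(self) -> None:
        for name in ("feedback_multiplier", "initial_receptor_multiplier", "ligand_multiplier"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v!r}")
        if self.dnfzd7_condition not in DNFZD7_CONDITIONS:
            raise ConfigurationError(
                f"unknown dnfzd7_condition {self.dnfzd7_condition!r}; "
                f"expected one of {DNFZD7_CONDITIONS}")

    def label(self) -> str:
        """Stable short identifier used in tables and file names."""
        parts = [f"fb{self.feedback_multiplier:g}",
                 f"ir{self.initial_receptor_multiplier:g}",
                 f"lig{self.ligand_multiplier:g}",
                 "sfrp1" if self.sfrp1_enabled else "nosfrp1",
                 "hs" if self.hs_enabled else "nohs"]
        if self.dnfzd7_condition != "none":
            parts.append(f"dn-{self.dnfzd7_condition}")
        return "_".join(parts)


class DnFzd7Params(NamedTuple):
    """Effective (p4, k5, k6, k7) for one dominant-negative condition."""

    p4: float
    k5: float
    k6: float
    k7: float


def dnfzd7_condition_params(condition: str, params: ModelParameters) -> DnFzd7Params:
    """Effective dnFzd7 parameters for one experimental condition.

    The four conditions dissect the two candidate functions of the
    dominant-negative receptor: ``both_functions`` keeps Wnt trapping
    (via k5, k6) and Fzd7 inactivation; ``inactivate_only`` removes the
    Wnt-binding reactions but keeps Wnt-catalysed heterodimerisation
    (k7 = k1); ``trap_only`` keeps homodimer Wnt trapping but removes
    heterodimer formation.  dnFzd7 is produced Wnt-dependently at
    p4 = 100·p3 whenever it is produced at all.
    """
    if condition == "none":
        return DnFzd7Params(p4=0.0, k5=params.k1, k6=params.k1, k7=0.0)
    if condition == "both_functions":
        return DnFzd7Params(p4=100.0 * params.p3, k5=params.k1, k6=params.k1, k7=0.0)
    if condition == "inactivate_only":
        return DnFzd7Params(p4=100.0 * params.p3, k5=0.0, k6=0.0, k7=params.k1)
    if condition == "trap_only":
        return DnFzd7Params(p4=100.0 * params.p3, k5=params.k1, k6=0.0, k7=0.0)
    raise ConfigurationError(
        f"unknown dnfzd7 condition {condition!r}; expected one of {DNFZD7_CONDITIONS}")


def effective_parameters(params: ModelParameters, scenario: Scenario) -> ModelParameters:
    """Fold a :class:`Scenario` into a plain parameter set.

    The dnFzd7 condition table is applied first (it is written in terms of
    the base feedback gain p3), then the scalar multipliers and on/off
    switches.  The result is an ordinary :class:`ModelParameters` usable by
    any code that knows nothing about scenarios.
    """
    dn = dnfzd7_condition_params(scenario.dnfzd7_condition, params)
    return params.replace(
        p4=dn.p4, k5=dn.k5, k6=dn.k6, k7=dn.k7,
        p3=scenario.feedback_multiplier * params.p3,
        p1=scenario.ligand_multiplier * params.p1,
        r0=scenario.initial_receptor_multiplier * params.r0,
        p2=params.p2 if scenario.sfrp1_enabled else 0.0,
        h0_amp=params.h0_amp if scenario.hs_enabled else 0.0,
    )


# ---------------------------------------------------------------------------
# spatial profiles

def _check_domain(x: ArrayLike, params: ModelParameters) -> NDArray[np.float64]:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > params.x_max):
        raise DomainError(f"position outside [0, {params.x_max}] μm")
    return x


def wnt_production_profile(x: ArrayLike, params: ModelParameters) -> NDArray[np.float64]:
    """Indicator f(x) of the epidermal Wnt6 source: 1 for x ≤ 10 μm, else 0."""
    x = _check_domain(x, params)
    return (x <= params.wnt_source_right_edge).astype(float)


def sfrp1_production_profile(x: ArrayLike, params: ModelParameters) -> NDArray[np.float64]:
    """Indicator g(x) of the myocardial sFRP1 source: 1 for x ≥ 25 μm, else 0."""
    x = _check_domain(x, params)
    return (x >= params.sfrp1_source_left_edge).astype(float)


def _bump(x: NDArray[np.float64], params: ModelParameters) -> NDArray[np.float64]:
    """sin(π(x−10)/15 − π/2) + 1 on bump_left < x < bump_right, else 0.

    Rises from 0 at 10 μm to its maximum of 2 at 25 μm and back to 0 at
    40 μm — the measured pericardial distribution of Fzd7 and N-acetyl HS.
    """
    half_period = (params.bump_right - params.bump_left) / 2.0
    inside = (x > params.bump_left) & (x < params.bump_right)
    phase = np.pi * (x - params.bump_left) / half_period - np.pi / 2.0
    return np.where(inside, np.sin(phase) + 1.0, 0.0)


def initial_receptor_profile(
    x: ArrayLike, params: ModelParameters, scenario: Scenario | None = None
) -> NDArray[np.float64]:
    """Initial Fzd7 concentration R₀(x) in nM (peak 2·r0 at x = 25 μm)."""
    x = _check_domain(x, params)
    mult = 1.0 if scenario is None else scenario.initial_receptor_multiplier
    return mult * params.r0 * _bump(x, params)


def initial_hs_profile(
    x: ArrayLike, params: ModelParameters, scenario: Scenario | None = None
) -> NDArray[np.float64]:
    """Initial (and, being immobile, permanent) total N-acetyl HS H₀(x) in nM."""
    x = _check_domain(x, params)
    if scenario is not None and not scenario.hs_enabled:
        return np.zeros_like(x)
    return params.h0_amp * _bump(x, params)


def hill_repression(omega: ArrayLike, params: ModelParameters) -> NDArray[np.float64]:
    """Repressive Hill factor 1 / ((ω/Kd)ⁿ + 1) on sFRP1 production.

    Equals 1 at zero signal, 1/2 at ω = Kd, and decreases monotonically to
    0: positions with high cumulative Wnt activity stop making antagonist.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise DomainError("omega must be >= 0")
    return 1.0 / ((omega / params.Kd) ** params.hill_n + 1.0)


# ---------------------------------------------------------------------------
# reaction right-hand side

def _mass_action_rhs(
    c: NDArray[np.float64],
    f: NDArray[np.float64],
    g: NDArray[np.float64],
    p: ModelParameters,
) -> NDArray[np.float64]:
    """Reaction-only time derivatives (no diffusion) for effective params ``p``.

    ``c`` has shape (14,) or (14, n_cells); ``f``/``g`` are the source
    indicators evaluated at the matching positions.  Internal kernel: does
    no input validation and tolerates the small negative excursions an
    implicit solver probes.
    """
    W, S, WS, H, SH, WSH, R = c[_IW], c[_IS], c[_IWS], c[_IH], c[_ISH], c[_IWSH], c[_IR]
    WR2, Dn, RD, D2, WD2, WRD, om = (
        c[_IWR2], c[_IDN], c[_IRD], c[_ID2], c[_IWD2], c[_IWRD], c[_IOM])

    v1 = p.k1 * W * R * R - p.k1_off * WR2          # W + 2R <-> WR2
    v2 = p.k2 * W * S - p.k2_off * WS               # W + S <-> WS
    v3 = p.k2 * W * SH - p.k2_off * WSH             # W + SH <-> WSH
    v4 = p.k3 * S * H - p.k3_off * SH               # S + H <-> SH
    v5 = p.k3 * WS * H - p.k3_off * WSH             # WS + H <-> WSH
    v6 = p.k5 * W * Dn * Dn - p.k1_off * WD2        # W + 2Dn <-> WD2
    v7 = p.k6 * W * R * Dn - p.k1_off * WRD         # W + R + Dn <-> WRD
    v8 = p.k7 * W * R * Dn - p.k1_off * RD          # R + Dn <-> RD (rate k7·[W])
    v9 = p.k7 * W * Dn * Dn - p.k1_off * D2         # Dn + Dn <-> D2 (rate k7·[W])
    internal = p.k4 * WR2                           # WR2 -> signal (ω)

    hill = 1.0 / ((om / p.Kd) ** p.hill_n + 1.0)

    out = np.empty_like(c)
    out[_IW] = -v1 - v2 - v3 - v6 - v7 + p.p1 * f
    out[_IS] = -v2 - v4 + p.p2 * hill * g
    out[_IWS] = v2 - v5
    out[_IH] = -v4 - v5
    out[_ISH] = v4 - v3
    out[_IWSH] = v3 + v5
    out[_IR] = -2.0 * v1 - v7 - v8 + p.p3 * internal
    out[_IWR2] = v1 - internal
    out[_IDN] = -2.0 * v6 - v7 - v8 - 2.0 * v9 + p.p4 * internal
    out[_IRD] = v8
    out[_ID2] = v9
    out[_IWD2] = v6
    out[_IWRD] = v7
    out[_IOM] = internal
    return out


def reaction_rhs(
    state: ArrayLike,
    x: ArrayLike,
    params: ModelParameters,
    scenario: Scenario | None = None,
) -> NDArray[np.float64]:
    """Reaction time-derivatives (nM/s) of all 14 state components at ``x``.

    ``state`` is (14,) for one cell or (14, n) for a profile; diffusion is
    *not* included (see :func:`wntgrad.solver.diffusion_operator`).  Raises
    :class:`IntegrityError` naming the offending species for NaN or negative
    concentrations.
    """
    c = np.asarray(state, dtype=float)
    if c.shape[0] != N_SPECIES:
        raise IntegrityError(f"state must have {N_SPECIES} components, got shape {c.shape}")
    for i, name in enumerate(SPECIES):
        row = np.atleast_1d(c[i])
        if np.any(np.isnan(row)):
            raise IntegrityError(f"NaN concentration in species {name!r}")
        if np.any(row < 0):
            raise IntegrityError(f"negative concentration in species {name!r}")
    eff = params if scenario is None else effective_parameters(params, scenario)
    f = wnt_production_profile(x, eff)
    g = sfrp1_production_profile(x, eff)
    return _mass_action_rhs(c, f, g, eff)


# ---------------------------------------------------------------------------
# state container

@dataclass(frozen=True)
class StateField:
    """Concentrations of all species plus ω on a spatial grid at one time.

    ``data`` is a (14, n_cells) array ordered as :data:`SPECIES`.  Small
    negative excursions within ``tol`` (the solver's working tolerance)
    are clipped on access through :meth:`clipped`; larger violations are
    structural failures.
    """

    data: NDArray[np.float64]
    tol: float = 1e-6

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != N_SPECIES:
            raise IntegrityError(f"StateField data must be (14, n_cells), got {d.shape}")
        if np.any(np.isnan(d)):
            raise IntegrityError("NaN in StateField")
        worst = d.min()
        if worst < -self.tol:
            bad = SPECIES[int(np.argmin(d.min(axis=1)))]
            raise IntegrityError(
                f"concentration of {bad!r} below -tol ({worst:.3e} < -{self.tol:.1e})")
        object.__setattr__(self, "data", d)

    def __getitem__(self, species: str) -> NDArray[np.float64]:
        return self.data[SPECIES_INDEX[species]]

    def clipped(self) -> NDArray[np.float64]:
        """Data with sub-tolerance negative excursions clipped to zero."""
        return np.clip(self.data, 0.0, None)

    @property
    def omega(self) -> NDArray[np.float64]:
        return self.data[_IOM]


# ---------------------------------------------------------------------------
# nondimensional layer (optional consistency check; dimensional form is
# normative throughout the package)

@dataclass(frozen=True)
class NondimensionalScaling:
    """Scale factors and the dimensionless parameter set.

    t* = t_max, c* = p1·t_max, and x* = sqrt(4·D·t*) so that the
    dimensionless diffusion coefficient D̃ = D·t*/x*² is exactly 1/4.
    ``scaled`` maps parameter names to their dimensionless values; the
    dimensionless groups (p3, p4, hill_n and the multipliers) pass through
    unchanged.
    """

    t_star: float
    x_star: float
    c_star: float
    scaled: dict[str, float] = field(default_factory=dict)


def nondimensionalize(params: ModelParameters) -> NondimensionalScaling:
    """Scale the parameter set to dimensionless form."""
    if not params.t_max > 0:
        raise ConfigurationError("t_max must be positive to nondimensionalize")
    t_star = params.t_max  # simulation starts at t_min = 0
    c_star = params.p1 * t_star
    x_star = float(np.sqrt(4.0 * params.diff_coef * t_star))
    if c_star <= 0:
        raise ConfigurationError("p1 must be positive to define the concentration scale")
    s = {
        "k1": params.k1 * c_star**2 * t_star,
        "k5": params.k5 * c_star**2 * t_star,
        "k6": params.k6 * c_star**2 * t_star,
        "k7": params.k7 * c_star**2 * t_star,
        "k2": params.k2 * c_star * t_star,
        "k3": params.k3 * c_star * t_star,
        "k1_off": params.k1_off * t_star,
        "k2_off": params.k2_off * t_star,
        "k3_off": params.k3_off * t_star,
        "k4": params.k4 * t_star,
        "p1": params.p1 * t_star / c_star,
        "p2": params.p2 * t_star / c_star,
        "p3": params.p3,
        "p4": params.p4,
        "Kd": params.Kd / c_star,
        "hill_n": params.hill_n,
        "diff_coef": params.diff_coef * t_star / x_star**2,
        "r0": params.r0 / c_star,
        "h0_amp": params.h0_amp / c_star,
        "x_max": params.x_max / x_star,
        "t_max": params.t_max / t_star,
        "wnt_source_right_edge": params.wnt_source_right_edge / x_star,
        "sfrp1_source_left_edge": params.sfrp1_source_left_edge / x_star,
        "bump_left": params.bump_left / x_star,
        "bump_right": params.bump_right / x_star,
    }
    return NondimensionalScaling(t_star=t_star, x_star=x_star, c_star=c_star, scaled=s)


def redimensionalize(scaling: NondimensionalScaling) -> ModelParameters:
    """Invert :func:`nondimensionalize`, recovering the dimensional parameters."""
    t, x, c = scaling.t_star, scaling.x_star, scaling.c_star
    s = scaling.scaled
    return ModelParameters(
        k1=s["k1"] / (c**2 * t), k5=s["k5"] / (c**2 * t),
        k6=s["k6"] / (c**2 * t), k7=s["k7"] / (c**2 * t),
        k2=s["k2"] / (c * t), k3=s["k3"] / (c * t),
        k1_off=s["k1_off"] / t, k2_off=s["k2_off"] / t,
        k3_off=s["k3_off"] / t, k4=s["k4"] / t,
        p1=s["p1"] * c / t, p2=s["p2"] * c / t,
        p3=s["p3"], p4=s["p4"], Kd=s["Kd"] * c, hill_n=s["hill_n"],
        diff_coef=s["diff_coef"] * x**2 / t,
        r0=s["r0"] * c, h0_amp=s["h0_amp"] * c,
        x_max=s["x_max"] * x, t_max=s["t_max"] * t,
        wnt_source_right_edge=s["wnt_source_right_edge"] * x,
        sfrp1_source_left_edge=s["sfrp1_source_left_edge"] * x,
        bump_left=s["bump_left"] * x, bump_right=s["bump_right"] * x,
    )
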