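# Methods

## The model

The package simulates extracellular regulation of the Wnt6 morphogen on a
one-dimensional strip x ∈ [0, 100] μm representing one lateral half of the
*Xenopus* heart field (bilateral symmetry motivates zero-flux boundaries at
both ends). Thirteen species evolve by mass action; three of them — free
Wnt6 (W), free sFRP1 (S) and the Wnt6·sFRP1 complex (WS) — also diffuse
with a shared coefficient D. The fourteenth state component is the
cumulative signalling activity ω(x, t) = k₄∫₀ᵗ [WR₂] dt′, the model's proxy
for pathway activation (β-catenin-dependent transcription); intracellular
transduction is treated as instantaneous and is not modelled.

Reactions (forward/backward rate constants in parentheses):

| reaction | rates |
|---|---|
| W + 2R ⇌ WR₂ → internalised (ω) | k₁ / k₋₁, internalisation k₄ |
| W + S ⇌ WS, W + SH ⇌ WSH | k₂ / k₋₂ |
| S + H ⇌ SH, WS + H ⇌ WSH | k₃ / k₋₃ |
| W + 2Dn ⇌ WD₂ | k₅ / k₋₁ |
| W + R + Dn ⇌ WRD | k₆ / k₋₁ |
| R + Dn ⇌ RD, Dn + Dn ⇌ D₂ (Wnt-catalysed, rate k₇·[W]) | k₇ / k₋₁ |
| ∅ → W at p₁·f(x); ∅ → S at p₂·g(x)/((ω/K_d)ⁿ + 1) | productions |
| ∅ → R at p₃·k₄[WR₂]; ∅ → Dn at p₄·k₄[WR₂] | feedback productions |

f(x) = 1 for x ≤ 10 μm (epidermal Wnt6 source), g(x) = 1 for x ≥ 25 μm
(myocardial sFRP1 source). Initial conditions are zero except sinusoidal
bumps of receptor and HS on 10 < x < 40 μm, R₀ = r₀[sin(π(x−10)/15 − π/2)+1]
(peak 2r₀ at 25 μm) and H₀ with amplitude h. Every dimer-forming reaction
consumes two monomers, so the monomer equations carry the factor 2 in both
directions; this is what makes the receptor moiety obey the closed-form
balance ∫(R + 2WR₂ + RD + WRD) dx = ∫R₀ dx + (p₃ − 2)∫ω dx, and the dnFzd7
moiety ∫(Dn + RD + 2D₂ + 2WD₂ + WRD) dx = p₄∫ω dx, which the test suite
checks continuously. HS is neither produced, degraded nor transported, so
H + SH + WSH is frozen per cell.

The dominant-negative receptor conditions are pure parameter rows:

| condition | p₄ | k₅ | k₆ | k₇ |
|---|---|---|---|---|
| none | 0 | k₁ | k₁ | 0 |
| both functions | 100·p₃ | k₁ | k₁ | 0 |
| inactivate-Fzd7 only | 100·p₃ | 0 | 0 | k₁ |
| trap-Wnt only | 100·p₃ | k₁ | 0 | 0 |

All scenario switches (feedback multiplier on p₃, initial-receptor
multiplier on r₀, ligand multiplier on p₁, sFRP1 off ⇒ p₂ = 0, HS off ⇒
h = 0, and the rows above) are parameter overrides on one fixed
right-hand side — there is exactly one code path for the dynamics. The
dnFzd7 row is applied using the base p₃ before the feedback multiplier
scales receptor production; the dissection experiments run at normal
feedback, where the two orderings coincide.

## Parameters

Defaults (units: nM, μm, s) are the wild-type set: k₁ = 2.66×10⁻⁶ nM⁻²s⁻¹,
k₋₁ = 9.6×10⁻⁵ s⁻¹, k₂ = 4.33×10⁻⁵ nM⁻¹s⁻¹, k₋₂ = 4.86×10⁻⁴ s⁻¹,
k₃ = 1.86×10⁻⁴ nM⁻¹s⁻¹, k₋₃ = 3.66×10⁻³ s⁻¹, k₄ = 2.52×10⁻⁴ s⁻¹,
p₁ = 10⁻⁴ nM s⁻¹, p₂ = 10⁻³ nM s⁻¹, p₃ = 10, K_d = 10⁻² nM, n = 2,
D = 20 μm² s⁻¹, r₀ = 75 nM, h = 10⁸ nM, x_max = 100 μm, t_max = 10⁵ s
(≈ one day of heart development). The parameters that drive the headline
behaviour are p₃ (feedback gain: 10 new receptors per internalisation,
against a stoichiometric cost of 2, so the receptor pool grows wherever
signalling runs), K_d (the signal level that silences sFRP1 production —
far below peak ω, so the antagonist is only made beyond the active
region), and h (so large that sFRP1 touching the 10–40 μm band is
immobilised on the spot).

A nondimensional layer (`nondimensionalize` / `redimensionalize`) is
provided as a consistency check; the dimensional equations are the
normative implementation. The time scale is t* = t_max (simulation starts
at t = 0), the concentration scale c* = p₁·t* = 10 nM, and the length
scale is taken as x* = √(4·D·t*) ≈ 2828 μm so that the dimensionless
diffusion coefficient D·t*/x*² is exactly 1/4; a scale of dimension
length² would not type-check, and the square-root reading is the unique
one consistent with the scaled diffusion term.

## Numerics

Space is discretised into uniform cell-centred finite-volume cells
(default 200 cells of 0.5 μm; grids below 20 cells are rejected because
the 10/25/40 μm region boundaries become unresolvable). A cell belongs to
a production region iff its centre satisfies the defining inequality, so
region semantics are grid-independent at the printed boundaries. Diffusion
is the 3-point Laplacian with reflecting ghost cells (discretely
conservative zero-flux boundaries).

The resulting 14·n ODE system is integrated with SciPy's BDF method,
rtol = 10⁻⁶, atol = 10⁻⁹ nM, 101 uniform output samples. Stiffness is
severe — k₃·2h ≈ 3.7×10⁴ s⁻¹ against a 10⁵ s horizon — so the solver is
given the exact Jacobian sparsity pattern (a dense 14×14 reaction block
per cell plus tridiagonal diffusion coupling for W, S, WS); a wild-type
full-scale run takes well under a second. The flattened state is
species-major (component i·n + j is species i in cell j, in the order
W, S, WS, H, SH, WSH, R, WR₂, Dn, RD, D₂, WD₂, WRD, ω).

Mass-action dynamics preserve non-negativity in exact arithmetic, so
large negative excursions indicate solver failure: anything below
−10³·atol aborts the run, smaller excursions are clipped to zero in saved
output only. ω is monotonised against round-off on output (it is a
cumulative integral by construction). Linear conservation laws are
preserved to near machine precision by the multistep scheme; the
conservation tests (10⁻⁶ per-cell HS, 10⁻⁴ global Wnt and Fzd7) pass with
orders of magnitude to spare.

Verification is two-pronged: (i) an independent fixed-step forward-Euler
transcription of the same equations (sharing no integration code) agrees
with the BDF solver to ≲ 10⁻⁴ relative L∞ on softened fixtures — the
explicit oracle cannot face h = 10⁸ nM, so those fixtures reduce h to
10³ nM and the full-stiffness regime is validated by the conservation
laws and by refinement instead; (ii) grid doubling (200→400 cells)
changes the final ω profile by < 0.04% and tolerance tightening
(rtol 10⁻⁶→10⁻⁸) by < 10⁻⁶ relative L∞.

## Derived quantities

The signal-active region at threshold θ is {x : ω(x) ≥ θ}. Its **edge** is
the rightmost crossing, located by linear interpolation between cell
centres, with sentinels 0 (never active) and x_max (active throughout);
the **width** is the measure of the super-threshold set of the
piecewise-linear profile (equal to the edge position for the usual
monotone profiles). Because the threshold the underlying experiments drew
is not a printed number, robustness statements are evaluated as dense
threshold sweeps (200 log-spaced levels over three decades below the
profile maximum — dense enough that the max-shift statistic is stable to
well under a micron); where a single level is needed (width and
settling-time summaries) the package uses 0.1× the final maximum ω of the
reference run, a mid-gradient level fixed once. The **edge shift**
between two runs is |edge difference| at the final time per threshold;
cross-condition comparisons use one shared sweep (up to the smallest
base-run maximum) so conditions are compared at identical signal levels.
**Time to steady edge** is the earliest sampled time after which the edge
stays within ε of its final position (ε = 1 μm, two default grid cells —
below biological relevance, above discretisation noise), quantifying how
vertical the threshold contour of the ω kymograph is.

## Experiments and fixtures

The four experiment pipelines are pure functions of (parameters, grid,
solver settings): feedback sweep (gain 0/1/5 × initial receptor 1/4),
ligand robustness (production 1.0 vs 1.5 for configurable
feedback/receptor combos), dnFzd7 dissection (the four condition rows),
and the sFRP1+HS contrast (both-on vs both-off, with the two mixed cases
available as extension outputs). Additional levels are configuration,
never code.

The fixture battery generates the deterministic study conditions at desk
scale: no-ligand and no-antagonist sector checks, a closed well-mixed
W+S system (relaxing to [WS]/([W][S]) = k₂/k₋₂ ≈ 0.0891 nM⁻¹), a
short-horizon full-stiffness run, a 1/10-duration miniature of the
wild-type scenario (50 cells, 10⁴ s — the conservation-suite workhorse),
and the softened oracle fixture (25 cells, 10³ s, h = 10³ nM). There are
no stochastic inputs anywhere: the model consumes no data and every run
is bit-reproducible. What the fixtures do *not* emulate is equally
important for interpreting green tests: no wet-lab measurement noise, no
embryo-to-embryo variability, no 2-D/3-D geometry, and no intracellular
signalling delay — passing tests certify the stated reaction-diffusion
model, not the biology beyond it.

## Design choices

* The dominant-negative receptor is named `Dn` (the field's symbol D
  collides with the diffusion coefficient).
* The homodimer monomer-consumption terms carry the factor 2 on both the
  forward and backward direction (the only reading under which the Fzd7
  and dnFzd7 moieties obey their closed-form balances, and the one
  matching the receptor equation's parenthesisation).
* ω is integrated as a state component (dω/dt = k₄[WR₂]) rather than by
  post-hoc quadrature, making the mass-balance identities exact at the
  discrete level.
* The Hill repression uses ω at the producing cell; the production term
  has no spatial coupling.
* Full-scale runs use 200 cells × 10⁵ s with 101 samples; the acceptance
  pipeline's settling-time contrast uses 1001 samples because the effect
  it resolves (a few hundred seconds) is smaller than the default
  sampling interval.

## Known limitations

* With the wild-type parameter set the sFRP1/HS module is a small
  correction at the normal receptor load: the receptor gauntlet absorbs
  almost all ligand before it reaches the antagonist-loaded zone, so
  enabling sFRP1+HS narrows the active region by only ~0.02 μm and
  changes the boundary-settling time by less than the default sampling
  interval (the settling contrast becomes strict and visible at reduced
  receptor loads, e.g. feedback 0 × receptor 0.25). Conclusions about
  antagonist timing at normal loads are below the model's effective
  resolution.
* The edge metrics assume a left-hand source geometry ("rightmost
  crossing"); profiles with detached distal islands report the outermost
  boundary.
* One spatial dimension, one shared diffusion coefficient, no receptor
  turnover other than signal-driven production and internalisation, and
  no saturation of HS binding sites (at h = 10⁸ nM they never fill).
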