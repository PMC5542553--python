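# Methods

## Model overview

`biofilmdem` simulates a microbial community as spherical agents on a
continuum nutrient background.  Agents carry position, core biomass
(femtograms of COD), an attached EPS-shell mass, velocity and a
functional-group label (heterotroph HET, nitrifiers AOB/NOB, free EPS
particle, inert).  A biological step comprises, in order:

1. quasi-steady solve of all solute fields with the current uptake sinks;
2. explicit-Euler growth/decay of each agent at its voxel's concentrations;
3. division, EPS excretion, death and removal (the stochastic events);
4. adhesive-link rebuild;
5. overdamped DEM relaxation to mechanical equilibrium, plus a window of
   advection when a shear flow is imposed.

Internally everything is in micrometres / femtograms / seconds; since
1 kg m⁻³ ≡ 1 fg μm⁻³, densities and concentrations carry over from SI
unchanged, spring constants convert by 10¹⁸ and viscosity by 10¹².

## Kinetics and the reaction network

Specific rates are products of a maximum rate, Monod terms `S/(K+S)` and
optional inhibition terms `K/(K+S)`; a stoichiometric table maps each
process onto particulate phases and solutes.  The single-species preset
(used by all headline studies) has HET growth on the carbonaceous
substrate with yield `Y` = 0.61 gCOD/gCOD and EPS formation
`Y_EPS` = 0.18 (a fraction `Y_EPS/(Y+Y_EPS)` of new COD goes to the EPS
shell), first-order HET decay `b`, and EPS/inert decay-to-substrate
switched off by default (negligible against growth).  A three-species
HET/AOB/NOB nitrification preset with ASM-style rate forms and typical
literature constants demonstrates the multi-species schema; its numbers
are representative, not canonical, and are drop-in replaceable through
the config.

Decaying active agents shrink core and shell proportionally (the split
is not observationally constrained; proportional decay avoids an
arbitrary ordering).  An agent shrinking to 0.8 μm diameter becomes
inert; its residual shell is released as a co-located free EPS particle
so that inert agents carry no shell and COD is conserved.  Anything at
0.1 μm is removed and ledgered.  Division triggers at 1.25 μm: daughter 1
keeps the mother's position and draws a mass fraction uniformly on
[0.40, 0.60] (half the mother mass ± 10 % of it); daughter 2 takes the
exact remainder, displaced along a uniform random direction at the sum of
the daughter radii (a `diameters` option reproduces the wider literal
spacing).  The shell splits in proportion to the daughter masses.  The
EPS shell is excreted as a free particle when the composite (core +
shell at EPS density) diameter reaches 1.25× the core diameter.

## Nutrient transport

The advection–diffusion–reaction equation is discretised on a uniform
cell-centred voxel grid: conservative central-difference diffusion with
arithmetic face diffusivities, first-order upwind advection (central
differences are unstable at voxel Péclet numbers of interest), and
forward-Euler pseudo-time marched to steady state, exploiting the
timescale separation between transport (seconds) and growth (hours).
Boundary conditions: periodic laterally; one z-wall is a Dirichlet feed
imposed on the wall face through a second-order ghost value, the other
zero-flux.  The feed wall is selectable (top = classical biofilm,
bottom = agar-plate-like growth, none = closed box for conservation
tests).

Monod sinks in dense voxels are stiff (depletion time ≪ diffusion time),
so the sink is linearised per voxel and treated semi-implicitly
(`S ← (S + dt(flux + sources))/(1 + dt c)`), which is
positivity-preserving and shares the explicit scheme's fixed point.
Reaction rates are refreshed every 50 pseudo-steps (chunked Picard);
convergence is declared when the per-step change falls below 10⁻⁵
(relative to the bulk concentration) — the converged field is
block-size-independent.  The effective diffusivity accepts a pluggable
relative-diffusivity closure `f(X) ∈ (0,1]`; the default is no biomass
hindrance (f = 1) since no closure constants are established here.

## Mechanics

Forces: Hookean (default) or Hertzian spring–dashpot contact with
normal and tangential components (`k_t = 2/7 k_n`, `γ_t = γ_n/2`,
a common granular-DEM convention; tangential spring history resets on
contact loss), walls as infinite-radius particles, EPS adhesion springs
of stiffness `k_eps·m_ij_eps` anchored at rest length `d0 = r_i + r_j`
and breaking permanently (within a relaxation phase) at `2 d0`, and
Stokes drag from the imposed shear flow.  Links form between pairs
within 1.1 `d0` whose combined EPS material (shells plus free-EPS
masses) is positive, and are rebuilt between biological steps.

Integration uses the overdamped limit of the equation of motion:
`v_i = U(z_i) + F_i/ζ_i` with `ζ_i = 6πμr_i`, advanced explicitly at
`dt = 0.1 ζ_min/k_max`.  Crowded contact networks stiffen the effective
spring; on detecting a velocity blow-up the step is halved and the phase
retried (floor 2⁻⁸ of the initial step).  Relaxation stops when the
internal virial pressure `P = (1/3V) Σ F_ij·d_ij` drops below a relative
tolerance (default 10⁻³ of its initial value) or a pseudo-time budget
elapses; pure-advection phases run a fixed flow window instead.  The
neighbour search is a numba cell list (periodic x/y, exact
minimum-image), rebuilt when accumulated displacement exceeds half the
skin.

The substratum can couple tangentially through the spring (default) or
a no-slip limit (`wall_friction: "no_slip"`), which pins wall-contacting
agents laterally — the behaviour of the stiff tangential spring that the
desk-scale (softened-spring) presets cannot otherwise reproduce.

## Morphometrics and detachment statistics

Height is per-column `max(z + r)`; roughness is the RMS height
fluctuation; porosity is `1 − ΣF/(N_x N_y h_max)` with `F` a voxel
occupancy indicator (sphere-intersects-voxel by default, centre-only by
flag) and `h_max` the height-field maximum in voxel units, recomputed
per snapshot.  Clusters are connected components of contact-overlap OR
active-adhesive-link adjacency; a component touching the substratum is
attached.  A detachment event is a component whose members were attached
at the previous check and no longer are; agents contribute to at most one
event (transient re-agglomeration is merged, not re-counted).  Cluster
volumes get a lognormal ML fit; the detachment rate is total detached
volume over time.

## Study conditions and the desk-scale presets

Full-scale presets encode the published study conditions: a
100×40×100 μm box with a 30×12×30 grid, 40-cell inoculum, growth stopped
at 15 % box volume, shear growth at γ̇/μ_m up to 144, and the detachment
case with the box doubled in x (outflow boundary), a film pre-grown to
48 μm and shear rates 0.04–0.24 s⁻¹.  These represent 4–16 days of
simulated growth and 10⁴–10⁵ agents; they carry `desk_scale=False` and
are not exercised by the test suite.

The trend suite runs desk-scale reductions chosen once and documented
here:

- **Geometry**: quasi-2D ribbons — 40×4×40 μm (30×3×30 grid) for growth
  and shear-growth, 48×4×24 μm (36×3×18, outflow x, film grown in the
  left half) for detachment.  A 4 μm depth (~4 cell diameters) keeps
  finger ridges from averaging out across y at these agent counts.
- **Inoculum**: 10 cells (8 for detachment), 1 μm diameter, evenly spaced
  with a small jitter; dense enough that colonies merge before the front
  instability develops.
- **Mechanics**: contact spring softened to 10⁻⁶ N m⁻¹ so the overdamped
  stability limit permits dt ≈ 10⁻³ s; EPS stiffness, viscosity and
  densities keep their full-scale values, preserving the drag/adhesion
  balance that controls erosion.  Densities are pinned at the full-scale
  ρ_X (≈ 6.2 kg m⁻³ COD-equivalent, with ρ_EPS = ρ_X/2) rather than
  re-derived from the reduced L_z, so agent masses — and with them the
  adhesive link strengths — stay at study scale.  The substratum runs in
  the no-slip limit (see above).  dt_bio = 2000 s: growth is
  transport-limited, so the per-step Euler increment stays small beyond
  the brief initial unlimited phase.
- **Nutrient conditions**: the (δ, κ) grid is (3×10⁻³, 0.35),
  (7×10⁻³, 0.70), (1.6×10⁻², 1.40), reached by scaling the bulk
  concentration and saturation constant.  The δ range was calibrated so
  the scaled runs reproduce the full-scale study's ~4× spread in
  growth-to-volume duration across the grid; at the nominal printed δ
  range the model reaches the stop volume with no duration spread at
  all, which is inconsistent with that reported spread (the nominal
  range appears to sit an order of magnitude too high for the reported
  dynamics).  κ spans its full nominal range.
- **Shear-growth rates**: the full-scale protocol shears continuously, a
  shear dose of γ̇·Δt_bio ≈ 40 strain units per biological step; the
  desk presets advect for 2 s per step, so the suite uses
  γ̇ ∈ {0, 0.1, 0.7} s⁻¹ — as close to that dose as the drag/adhesion
  balance allows (beyond ~0.7 s⁻¹ drag exceeds the break force of mature
  links and the film shreds rather than smooths).
- **Detachment**: films grown at (7×10⁻³, 0.35) to 12 % box volume, then
  90 s of shear in 1 s windows at 0.04/0.12/0.24 s⁻¹ — the published
  range — applied to the *same* film per replicate (paired design).

What the passing trend suite shows: the emergent directions — rougher,
more porous films at low δ,κ; smoother films under stronger shear or
bottom feeding; more, smaller detachment events at higher shear with a
rise-then-fall event-count history — are properties of the model, robust
across seeds at desk scale.  What it does not show: quantitative
agreement with full-scale magnitudes (desk films are ~10³ agents, so
detached clusters are relatively far larger than at full scale), or any
statement about real biofilms beyond the model's assumptions.

## Synthetic data

All inputs are generated: the inoculum generator places 1 μm cells on
the substratum (even grid + jitter, or one HET/AOB/NOB triplet at the
centre for the multi-species demo).  It emulates the standard
even-inoculation protocol; it does not emulate surface conditioning
films, irregular attachment kinetics or cell-size variability.

## Numerical choices and degenerate inputs

- Quasi-steady tolerance 10⁻⁵ (relative per-step change), Picard block
  50; solver warm-starts from the previous step's fields.
- Contact between coincident centres falls back to a +z normal (warned).
- Zero-height biofilms return porosity 0 with a degeneracy flag;
  empty populations give zero volume fractions and empty statistics.
- Event order within a step (division → excretion → death/removal, agents
  in index order, one RNG stream) makes runs bit-reproducible per seed.
- The biomass Euler scheme has a known compounding bias ~r²·dt·t/2; at
  full Monod saturation and dt = 100 s this is ~7 % over 10 h, so oracle
  comparisons against `m₀e^{rt}` are made at moderate saturation where
  the bias is ≲ 0.6 %.

## Known limitations

- One-way fluid coupling only: the imposed shear is undisturbed by the
  biofilm, so interior agents feel full flow; sheltering is absent.
- No rotational degrees of freedom or Coulomb friction cap; tangential
  springs act as unbounded anchors while contact persists.
- The overdamped integrator removes inertial dynamics; viscoelastic
  creep timescales are therefore compressed relative to inertial DEM.
- Solute fields remain x-periodic in outflow domains (solute outflow is
  not modelled); acceptable because detachment phases are short against
  transport timescales.
- Desk-scale detachment strips most of the small films at all rates;
  the suite reads trends (event counts, mean cluster size), not absolute
  detached fractions.
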