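# Methods

This document describes the modeling formalism implemented by `tkm`,
the design of the packaged core fixture, the numerical methods, and the
known limitations of the fixture.

## 1. Thermokinetic formalism

### 1.1 Capacities and potentials

Each metabolite i in a compartment at electric potential ϕ has a
*capacity*

    C_i = c° · exp(−(μ″°_i + z_i·F·ϕ) / (R·T))

with μ″°_i the transformed standard Gibbs formation energy at the
model's fixed temperature, pH, water activity, and ionic strength
(Debye–Hückel corrected, Alberty's extended form), z_i the dominant
charge at pH 7, and c° = 1 mol/l. The *thermokinetic potential* of the
species is ξ_i = c_i / C_i; ξ is a dimensionless activity-like variable
that absorbs all of the species' thermodynamics. Capacities that would
over- or underflow double precision raise `CapacityRangeError` rather
than silently saturating.

### 1.2 Forces, resistances, fluxes

For a reaction j with stoichiometry ν (reactants negative):

    F_j = ∏_{ν<0} ξ_i^{|ν|} − ∏_{ν>0} ξ_i^{ν}

is its *force*: positive exactly when the reaction is thermodynamically
downhill. A kinetic reaction has a *resistance*

    R_j = k_{+j}^{−1} · ∏_{reactants} C_i^{−|ν|} · ∏_{modifiers} m(ξ)

where k_{+j} = 10^x with integer x (kinetic parameters are restricted
to decades — the formalism's deliberate coarse-graining of kinetics),
and each modifier multiplies R by (1 + ξ_m/θ) for an inhibitor or its
reciprocal for an activator. The flux is

    J_j = c_{E_j} · F_j / R_j ,

so sign(J) = sign(F) for any positive enzyme level: thermodynamic
consistency is built into the rate law. Quasi-equilibrium (QE)
reactions carry no finite resistance; their flux is an algebraic
unknown and their constraint is F_j = 0, imposed in log-potential space
as Σ ν_ij · ln ξ_i = 0. Enforced drains (used in production
assessment) clamp J to a given value and bypass the rate law.

Because capacities derive from formation energies, equilibrium
constants are automatically Wegscheider-consistent: around any
stoichiometric cycle the ln K's sum to zero (tested against the null
space of the core stoichiometry).

### 1.3 Regulation

A transcription factor reads one scalar signal s (an arithmetic
expression over concentrations, e.g. the reduced quinone fraction) with
a Hill activity a = s^n / (s^n + k_half^n); n may be negative
(repression by the signal). A gene's synthesis rate is its basal rate
times one *expression modifier* per regulator,

    s(k, a) = 2^{−k} + (1 − 2^{−k})·a ,

with integer strength k (again decades-of-two coarse-graining);
inhibiting regulators enter with 1 − a. Enzyme levels obey
dc_E/dt = J_syn − μ·c_E, so at steady state c_E = J_syn/μ = J_syn/D.

### 1.4 Population and chemostat

Growth follows a linlog law: μ = ramp(c_ATP/c_ADP; k_lo, k_hi) ·
max(0, k_a·(k_b + Σ ν_i ln c_i)) over the biomass precursors. The
ramp is zero below k_lo — growth stops when the adenylate state
collapses. Maintenance ATP hydrolysis uses the same ramp shape with
its own window, plus an *overdrive* term: above the window the
hydrolysis keeps rising at a small fraction (5% in the core fixture) of
the in-window slope. This represents futile ATP cycling at high energy
charge and keeps the ATP/ADP ratio bounded on strongly aerated
branches; without it the maintenance sink saturates while the
respiratory chain keeps charging the pool.

The chemostat balances biomass ((μ−D)·c_X = 0), dissolved species
(D·(c_in − c) + J·c_X = 0), and gas species (k_in − k_out·c + J·c_X = 0).
Intracellular species are balanced per gram dry weight with a growth
dilution term μ·c·v_cell. Conserved moiety pools (adenylates,
nicotinamides, NADP, CoA) are held at fixed totals with a de-novo
synthesis flux μ·total balancing growth dilution, injected at a
designated member.

### 1.5 Operational aerobiosis scale

Aerobiosis is *operational*: 0% is the anaerobic culture, and 100% is
defined as the oxygen supply at which specific acetate excretion has
fallen to 0.5% of its anaerobic value. `calibrate_oxygen_supply`
bisects the absolute supply k_in,100 to find that point; intermediate
aerobiosis a scales the supply linearly, k_in = a/100 · k_in,100.
Quinone pool totals ramp linearly with a (ubiquinone up, menaquinone
down) and clamp above 100%, mimicking the cell's adjustment of its
quinone complement. For production assessments the *absolute* aeration
is frozen (at 160% of the undisturbed culture's supply for the aerobic
operating point), since the perturbed culture's own aerobiosis shifts
as c_X changes.

### 1.6 Production assessment

A production pathway is abstracted as an enforced drain with explicit
stoichiometry (e.g. `pyr + nadh -> etoh_e + co2 + nad`). Drains must
conserve the model's moiety pools — a drain that consumed NADH without
returning NAD would destroy the nicotinamide pool and is rejected at
validation. The demand grid starts on [0, demand_max], doubles upward
while the culture sustains the highest demand, and then bisects the
collapse edge for a configurable number of refinement rounds. All
reported concentrations are relative to the same run's zero-demand
state; volumetric productivity is q_prod = J_prod·c_X identically. The
limiting precursor is the drained species with the largest relative
drop at the last converged point (ties reported, not broken).

Measured data are relative in general; `overlay` scales each measured
variable by f = (x_s·x_s)/(x_m·x_s) — the least-squares factor
minimizing ‖(1/f)·x_s − x_m‖² — while flux-like variables are compared
absolutely (f = 1).

## 2. The core fixture

`build_fixture("core")` generates a deterministic ~35-reaction model of
*E. coli* central metabolism: PTS uptake, glycolysis (PGI, FBA, TPI,
ENO as QE; PFK with ADP activation; GAPD; PYK), anaplerosis (PPC), an
oxidative PP branch (GND plus a lumped QE transketolase), overflow
metabolism (PDH, PFL, PTA-ACK, ADHEr with transport steps), a full TCA
cycle with both the cyclic (SUCDH) and branched (FRD) succinate-fumarate
steps, and an electron transport chain with ubiquinone and menaquinone
pools, NADH dehydrogenases I/II, cytochrome oxidases bo3 and bd, ATP
synthase, transhydrogenases, and a proton leak. ArcA (sensing the
reduced quinol fraction) and FNR (sensing dissolved O2) regulate the
fermentative and respiratory branches with integer strengths (e.g. pfl
activated +2 by both, cyo repressed −2 by ArcA).

All kinetic constants are integer decades; enzymes have uniform basal
synthesis so that regulation, not per-gene tuning, differentiates
expression. The growth law is calibrated so the anaerobic reference
runs glucose-limited at D = 0.2/h with c_X ≈ 0.256 g/l and specific
acetate excretion ≈ 9.4 mmol/gDCW/h. Variants: `toy` (4-reaction
chain), `include_regulation=False`, `include_etc=False` (fermentative
subnetwork only; TF layer removed because both signals sense the ETC).
All variants round-trip exactly through the `.tkm` parser/serializer.

## 3. Numerics

The steady state is a damped Newton solve (finite-difference Jacobian,
line search, log-space potentials for positivity) on the full residual
[intracellular, QE, extracellular, growth] with a pseudo-transient
fallback (implicit Euler with geometrically growing steps) when Newton
stalls; washout is detected either as a converged zero-biomass state or
a collapsing trajectory with μ < D.

Two numerical floors are handled explicitly. Near-equilibrium
reactions carry gross one-way fluxes up to ~100× their net flux, so
floating-point cancellation puts a residual noise floor near 1e-9 at
strongly aerated states. The Newton solver therefore accepts a stalled
iterate whose residual is within 10× the tolerance after five
non-improving steps, and production assessments default to tol = 1e-8.
Both concern residual bookkeeping only; no model behavior is evaluated
at those floors.

Sweeps are continuation runs: each converged point warm-starts the
next, failed points are flagged rather than dropped, and a failing
first point aborts. The aerobiosis calibration and the aerobic
assessments cross a fold at acetate extinction; both walk the oxygen
supply with recursive step-bisection and treat a fold as the high side
of the bisection. Washout detection at dilution rates above the
achievable growth rate needs a long pseudo-transient horizon
(≈ 400 h), because biomass decays only at rate |μ − D|.

## 4. Known limitations of the core fixture

- **NADH is not monotone along the aerobiosis scale.** The reduction
  state peaks microaerobically (a ≈ 7.5) and rebounds by ≈ +32% over
  the top of the scale. The cause is structural: 100% aerobiosis is by
  definition the *marginal* oxygen supply (acetate just vanishes), so
  dissolved O2 remains scarce at the top of the scale, the quinol pool
  partially re-reduces there, and the near-equilibrium NADH
  dehydrogenase I slaves the NADH/NAD ratio to the quinol fraction.
  Retuning the oxidases, the ArcA half-point, or the ADH regulation
  shifts but does not remove the effect.
- **The raw ATP/ADP ratio drifts under a large enforced ATP drain**
  (−18% at J_prod = 8 mmol/gDCW/h, more beyond). In a glucose-limited
  chemostat the volumetric ATP production is fixed by the feed, so a
  rising per-gram demand must shift the adenylate state; the
  PFK-by-ADP activation cannot compensate for a supply that cannot
  grow. The adenylate *energy charge*, buffered by the QE adenylate
  kinase, is what stays near-constant (−0.5% at J_prod = 8, −5% at 32).
- **Lower-glycolysis intermediates rise with dilution rate.** fdp and
  dhap correctly rise with D, but pep/3pg also rise slightly instead of
  falling; lowering the GAPD resistance enough to reverse them pushes
  fdp to molar scale or breaks convergence.
- Cold starts far from the D = 0.2/h design point can fail to converge;
  sweeps should start near the design point and continue outward.
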