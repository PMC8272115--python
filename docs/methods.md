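# Methods

## Model

The package simulates a three-component linear polymer mixture in explicit
solvent with dissipative particle dynamics (DPD). All quantities are in
reduced units: the interaction cutoff R_c, the bead mass m and the thermal
energy k_BT define the unit system (R_c = m = k_BT = 1), and τ =
√(m R_c²/k_BT) is the time unit.

Each pair of beads i, j within the cutoff interacts through three forces:

* a soft conservative repulsion  F^C = a_ij (1 − r/R_c) ê_ij,
* a dissipative drag             F^D = −γ (1 − r/R_c)² (v_ij·ê_ij) ê_ij,
* a random force                 F^R = σ (1 − r/R_c) ξ_ij Δt^(−1/2) ê_ij,

with ξ_ij a zero-mean, unit-variance Gaussian drawn once per interacting
pair per step and symmetric under index exchange. The weight functions obey
w_D = w_R², and σ² = 2 γ k_BT, so the dissipative/random pair satisfies the
fluctuation–dissipation theorem and thermostats the system at k_BT while
conserving momentum exactly (every pair contribution is antisymmetric).
Consecutive beads of a chain are additionally tied by a harmonic spring
F^S = −C r_ij with zero rest length; bonded pairs also feel the nonbonded
forces (no exclusions).

Bead species are A (solvophobic), S (solvophilic) and W (solvent). The
molecular species are the solvophobic homopolymer A₁₉, the amphiphilic
di-block copolymer A₁-b-S₆, the solvophilic homopolymer S₆ and monomeric
solvent W.

### Parameters

| parameter | value | meaning |
|---|---|---|
| ρ | 3 | reduced bead density (beads per R_c³) |
| a_ii | 25 | like-species repulsion, from a_ii = 75/ρ (water compressibility) |
| a_AS | 72 | A–S repulsion (χ ≈ 14.37): strong mutual incompatibility |
| a_SW | 30 | S–solvent repulsion (χ ≈ 1.53): mildly solvophilic |
| a_AW | 115 | A–solvent repulsion: strongly solvophobic |
| C | 4.0 | harmonic bond constant |
| γ, σ | 4.5, 3.0 | thermostat pair (σ² = 2γk_BT); the standard choice for this density — the source study does not state them |
| Δt | 0.05 τ | time step |
| λ | 0.65 | velocity-prediction factor of the modified velocity-Verlet scheme |

Cross repulsions map linearly onto the Flory–Huggins parameter at ρ = 3:
a_ij − a_ii ≈ 3.27 χ_ij. The implementation reports χ from this relation
throughout; note that for a_AW = 115 it gives χ = 27.52 (the value sometimes
quoted for this amplitude, 27.72, is not consistent with the linear map and
is not used).

### Integrator

The modified velocity-Verlet (λ) scheme with one force evaluation per step:

    r ← r + Δt v + ½Δt² f
    ṽ ← v + λ Δt f
    f′ ← F(r, ṽ)            (the dissipative force uses the predicted ṽ)
    v ← v + ½Δt (f + f′)

At Δt = 0.05 and λ = 0.65 the kinetic temperature of an equilibrated
solvent box sits within ~1% of the target, which the acceptance suite
checks directly.

## System construction

A box of edge L at density ρ holds round(ρL³) beads. Chain counts are
round(pct/100 · N / chain length) per species; the bead remainder is
assigned to solvent, so the total density is exact and the composition
deviates from the nominal 4/13/3/80% by well under 0.1% at the box sizes
used. Initial chains are freely jointed random walks with step 0.7 R_c
(the equilibrium bond length is ≈0.85 R_c under C = 4 with the soft
repulsions); solvent is uniform; velocities are Maxwell–Boltzmann at
k_BT = 1 with the net momentum removed. Soft DPD potentials tolerate the
resulting overlaps, but the stored overlap energy produces a short violent
transient (kinetic T ≈ 3 for roughly the first hundred steps, decaying to
1 well within 10³ steps). The transient is harmless in production boxes;
in boxes smaller than ~10 R_c it can transiently stretch a bond past the
half-box minimum-image limit, which the engine reports as an integration
error, so dynamical runs in this package use boxes of edge ≥ 10 R_c.

## Aggregate analysis

* **Clustering.** Any two analyzed beads within 1.5 R_c (minimum image)
  belong to the same aggregate; aggregates are connected components of
  this proximity graph (single linkage). Whole-aggregate analysis runs on
  polymer beads only — the solvent percolates the box and would connect
  everything.
* **Size statistics.** X̄n = ΣX_iN_i/ΣN_i, X̄w = ΣX_i²N_i/ΣX_iN_i,
  polydispersity P = X̄w/X̄n ≥ 1, with N_i the number of aggregates of
  X_i beads.
* **Order parameter.** The box is sliced into N slabs of equal thickness
  (default: one per R_c) perpendicular to a chosen axis; in each slice the
  volume fractions φ_A, φ_B of two designated components are bead-count
  fractions among all beads in the slice (equal bead volumes in DPD), and
  φ = ⟨|φ_A − φ_B|⟩ over slices. Empty slices contribute 0. Two component
  resolutions are reported: polymer-vs-solvent (aggregate segregation) and
  A-homopolymer-vs-everything-else (core segregation).
* **Shape.** Clusters are unwrapped by breadth-first traversal of the
  proximity graph, placing each bead at its minimum image relative to its
  discovered parent; if a cluster is connected to one of its own periodic
  images the unwrap is ambiguous (the cluster percolates) and the shape is
  undefined for that frame. The gyration tensor about the centroid gives
  principal moments λ₁² ≥ λ₂² ≥ λ₃² and the asphericity
  δ = [(λ₁²−λ₂²)² + (λ₁²−λ₃²)² + (λ₃²−λ₂²)²] / [2(λ₁²+λ₂²+λ₃²)²],
  0 for a sphere, ¼ for a flat disk, 1 for a line. Note that an extent
  larger than half the box is *not* by itself an error — at 20% polymer
  the equilibrium droplet diameter always exceeds L/2 — only genuine
  self-image connection is.
* **Cores.** Within each aggregate, the solvophobic-homopolymer beads
  (and, separately, the S-homopolymer beads) are re-clustered at the same
  1.5 R_c criterion. A cluster counts as a *condensed core* only if it has
  ≥ 20 beads (≈ one A₁₉ chain) and is condensed: its beads average ≥ 6
  same-cluster neighbors within 1 R_c (a dense droplet at ρ = 3 sits near
  10) *or* average ≤ 2.5 solvent beads within 1 R_c (a solvent-excluded
  compartment — compartments of short chains can be irregular and locally
  dilute yet clearly buried). The condensation requirement is essential:
  S₆ chains dispersed through a solvent-swollen corona routinely touch one
  another at 1.5 R_c and form large but loose clusters (measured ≈ 2–4
  same-species neighbors and solvent exposure ≈ 3–7), which a bare
  distance criterion would misread as compartments, while genuine S
  compartments measure ≈ 4.4 neighbors but only ≈ 1.5 solvent contacts.

## Morphology classification

Equilibrated frames are labeled by rules evaluated on the largest polymer
aggregate (majority vote over the last 10 stored frames; disagreement or
near-threshold values set an ambiguity flag rather than silently coercing):

1. *dispersed* — the largest aggregate holds < 5% of the polymer beads, or
   contains no condensed core of either chemistry;
2. *soluble-particle* — A cores exist, but the mean copolymer coverage of
   their surfaces is < 0.5 (coverage = fraction of core surface beads with
   a copolymer A bead within 1 R_c; surface beads are core beads with
   < 10 same-core neighbors within 1 R_c). The coverage radius is one
   coordination shell rather than the 1.5 R_c cluster cutoff because at
   these concentrations freely dissolved copolymer produces near-unit
   incidental contact at 1.5 R_c (measured: 1.00 for the reference system
   *and* 0.49 for the nearly-soluble a_AW = 35 state), whereas at 1 R_c
   the adsorbed layer still reads ≈ 0.98 while bystander chains give
   ≈ 0.23;
3. *multicore–multicompartment* — at least one condensed A core and at
   least one condensed S core in the same aggregate;
4. *multicore* — ≥ 2 A cores, no S cores;
5. *single-core* — exactly one A core.

## Kinetic stages

The assembly proceeds through (I) micelle nucleation — both the core and
whole-aggregate X̄n rise, (II) micelle coalescence — core sizes saturate
while the whole-aggregate size keeps rising, (III) equilibrium — both
plateau. Stage boundaries are detected on the X̄n series of the global
A-homopolymer clustering (cores) and of the polymer clustering (whole
aggregates). A series has settled at the first snapshot from which the
remaining series shows no net drift: a straight line is fit to the tail,
and the fitted net change must be within 5% of the tail level or within
twice the statistical uncertainty of the fitted change given the tail's
own fluctuations. The noise allowance matters at desk scale, where the
number-average is dominated by the fluctuating count of stray chains
(one droplet plus k ≈ 3–11 strays makes X̄n ≈ N/(k+1) swing by ±40%
between snapshots) and a pure spread criterion would never fire; the
drift form detects "stabilizes at a constant level" robustly and reduces
to the plain 5% rule on low-noise series. Both series are lightly
smoothed (centered 10-snapshot running mean) first. If the
whole-aggregate series never settles the run is reported "not
equilibrated" (a result, not an exception).

## Desk-scale study conditions

The reference study box is (40 R_c)³ (192,000 beads, 5×10⁵–5×10⁶ steps);
quantitative expectations at that scale are recorded machine-readably in
`dpdmc.targets.FULL_SCALE_TARGETS` with `desk_scale: False` and are not
asserted by the desk-scale suite. The package's own analyses run at desk
scale:

* reference assembly: box 15 R_c (10,125 beads), 2×10⁵ steps, snapshots
  every 10³ steps;
* solvent-selectivity transition points: box 10 R_c (3,000 beads),
  5×10⁴ steps for the a_AW = 35 point and 7×10⁴ steps for a_SW = 65.

Box size rescales the amount of material, and with it what equilibrium
desk-scale runs can show. The equilibrium core size of this model is a few
hundred A beads, so a 15 R_c box (399 A beads, ~1.6 cores' worth of
solvophobe) coarsens to a *single* condensed core within ~10⁴ steps: the
multicore state of the large-box system is not reachable at this scale,
and desk runs of the reference system classify as single-core. Larger
desk boxes (18–20 R_c, 2–3 cores' worth) are exposed through the same
drivers for longer experiments. What desk runs do reproduce faithfully:
the three kinetic stages, the spherical equilibrium aggregate
(δ < 0.01 averaged over the final snapshots, excluding frames where a
transiently attached stray chain bridges the aggregate to its periodic
image), the loss of aggregation when the solvophobe is made nearly
soluble (a_AW → 35), and the appearance of condensed S compartments when
the solvophile is made solvophobic (a_SW = 65).

## Numerical choices

* Pair search: linked cells (width ≥ R_c, half-shell enumeration, exact
  minimum image); an all-pairs path covers boxes < 3 R_c. The cell walk and
  the dynamics kernel share the same machinery, and the pair enumeration is
  verified against an O(N²) oracle.
* The master state (positions, velocities, force accumulators) is float64.
  The cell-sorted working copies inside the pair loop are float32 — pair
  geometry needs ≤ 1e−7 relative accuracy, far below thermal noise — and
  every pair force value is widened to float64 *before* being added to bead
  i and subtracted from bead j, so antisymmetry (and momentum conservation,
  < 1e−6 drift over 10⁵ steps) holds to float64 rounding.
* Gaussian noise comes from a 128-layer ziggurat sampler driven by an
  explicit xorshift128+ state, seeded once per run; runs are bitwise
  reproducible for a given seed. The sampler's output is checked
  distributionally (moments and a KS test) in the suite.
* Degenerate geometry: exactly coincident beads (r = 0) exchange no
  nonbonded force (the direction is undefined; the event has probability
  zero); zero-length bonds exert no force; a bond longer than half the box
  aborts integration with an error naming the step, since its minimum
  image is ambiguous.
* Cluster unwrapping detects percolation by image-offset consistency, not
  by extent (see above). Frames whose largest aggregate percolates are
  excluded from shape averages and reported as NaN.

## Known limitations

* Desk-scale boxes cannot hold several equilibrium cores of the reference
  chemistry; multicore morphology at the reference parameters needs boxes
  ≳ 18 R_c and correspondingly longer runs (see above).
* The stray-chain population makes number-average sizes noisy at desk
  scale; stage detection therefore smooths before change-point search.
* The classifier's coverage and condensed-core thresholds are documented
  heuristics calibrated on the geometry of this model (condensed droplets
  vs corona-dispersed chains at ρ = 3); they are parameters, not claims.
* No pressure coupling, electrostatics, or angle/dihedral terms; the
  engine is NVT-only by design.
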