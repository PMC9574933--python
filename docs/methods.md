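# Methods

## Model

Beads interact through the standard DPD force set.  The conservative
repulsion is linear, **F**^C = a_ij (1 − r/R_ij^C) r̂ for r < R_ij^C,
zero beyond; unusually for DPD, *both* the repulsion a_ij and the
cutoff R_ij^C vary per species pair, which lets beads of different
molar volume coexist.  The solvent–solvent cutoff R_WW^C = 1 defines
the reduced length unit.  The dissipative and random forces form the
thermostat: **F**^D = −γ ω^D(r)(r̂·**v**_ij) r̂ and
**F**^R = σ ω^R(r) ζ_ij Δt^(−1/2) r̂ with ω^D = (ω^R)² =
(1 − r/R_ij^C)² and σ² = 2γk_BT (fluctuation–dissipation).  The
dissipative/random pair uses the same pair-specific cutoff as the
conservative force; the alternative (a fixed unit cutoff for the
thermostat) is a defensible reading, but using one cutoff per pair
keeps the weight functions consistent and is what the implementation
asserts in its property tests.

Chains are held by harmonic bonds U^B = (C/2)(r − l₀)² and straightened
by harmonic angles U^A = (D/2)(θ − θ₀)², with C = 150, D = 5,
θ₀ = 180°.  The unstretched bond length grows with the number of heavy
atoms (C, O, S) in the bonded beads; the shipped rule is
l₀ = 0.1(nᵢ + nⱼ) and is config-replaceable by an explicit pair table.
The five species are W (2 H₂O), C (3 alkyl carbons; the C12 tail is
four beads), E (CH₂OCH₂), S (OSO₃⁻) and Na (hydrated Na⁺).  Bead
masses are all 1.

Charged beads carry Slater-type exponential charge clouds:
u(r) = Γ q_i q_j/(4πr) [1 − (1 + β*r) e^(−2β*r)], finite at contact
(Γ q_i q_j β*/4π) and Coulombic at long range, with β* = 0.929 and
Γ = e²/(k_B T ε₀ ε_r r_C) ≈ 15.9 for ε_r = 78.3 at 25 °C.  Periodic
sums use Ewald splitting: the point-charge part splits into an erfc
real-space sum and a reciprocal sum (triclinic reciprocal basis under
Lees-Edwards tilt), and the exponentially short-ranged smearing
correction is summed in real space over every image within its decay
range — this matters for boxes smaller than twice that range (~6 r_C)
and is validated against a direct image-sum reference on zero-dipole
systems.  Splitting parameter, real cutoff and reciprocal extent are
auto-tuned to ~1e-4 relative force accuracy.

## Units

Reduced units: r_C = m = k_BT = 1.  The SI mapping matches the
coarse-grained water mass density (2 H₂O per bead, ρr_C³ = 3) to
997 kg/m³ at 298.15 K with CODATA constants, giving r_C ≈ 5.65 Å,
m ≈ 5.98×10⁻²⁶ kg, k_BT ≈ 4.12×10⁻²¹ J and the derived time scale
τ = r_C√(m/k_BT) ≈ 2.15×10⁻¹² s.  Exact recomputation of the time
step in SI gives 2.153×10⁻¹⁴ s; tables that round the intermediate
scales to three figures before multiplying obtain 2.16×10⁻¹⁴ s, and
the tests accept agreement within one unit in the third significant
digit for this reason.

## Integration and reproducibility

The engine uses the DPD modified velocity-Verlet scheme with
prediction parameter λ = 0.65 and Δt = 0.01: positions advance with
the old force, the new force is evaluated once at the predicted
velocities, and the velocity update averages old and new forces.  At
these settings the long-run kinetic temperature of pure water at
ρ = 3 sits in [0.98, 1.05] (asserted over 10⁴ steps at L = 10), and
breaking the σ²=2γkT link (σ = 3, γ = 2) measurably overheats the
system — a negative control in the suite.

Thermostat noise is counter-based: ζ_ij at a given step is a pure
splitmix64 hash of (seed, step index, sorted bead pair), so
ζ_ij = ζ_ji exactly, brute-force and cell-list sweeps agree to
accumulation rounding (≤1e-12), results are independent of thread
count, and a checkpoint restart (which carries the cached force of the
predictor stage) continues bitwise.  The cell-list sweep gathers beads
into cell-sorted arrays and precomputes the periodic image shift per
neighbour-cell pair; under an active Lees-Edwards offset the columns
across the sheared boundary are misaligned, so that path falls back to
a full-shell sweep whose y-wrapping rows scan all x columns.

Lees-Edwards shear: images across the y boundary are displaced in x by
an offset advancing at γ̇ L per unit time (mod L) and move at relative
x-velocity γ̇ L.  Sheared water develops a linear velocity profile
with slope γ̇ (verified to within 10% by block-averaged binning).  The
default shear rate is 0.01 reduced units and is config-exposed; tests
use 0.05 so the profile rises cleanly above thermal noise at desk
scale.

## Analyses

**Micelles.**  Two molecules are in contact when any pair of their
tail beads lies within 1 r_C (periodic minimum image); micelles are
connected components at molecule granularity, and whole molecules
follow their tails.  N_agg is the unweighted mean over micelles
(mass-weighting is available but not the default); free monomers are
included.  Clusters are unwrapped by BFS over the contact + bond graph
with image bookkeeping; inequivalent image paths or extents beyond L/2
flag percolation, where R_G is reported with a warning.  Equilibration
is declared at the earliest 5000-time-unit block whose own and all
later block means lie within one pooled (within-block) standard
deviation of their joint mean; pooling within-block variances makes a
noise-free ramp unequilibrated while a noisy plateau passes from its
first block.  The sphericity profile bins R_G³/N in aggregation-number
bins of width 5 and reports the per-bin micelle-pooled standard
deviation; the most-spherical size N* is the vertex of a quadratic
through the lowest bin and its two neighbours, and is reported
undefined for flat, edge-minimum or non-convex profiles.
Compositional mixing of polydisperse micelles is scored per micelle by
the Pearson χ² distance to the global ethoxylation mixture with a
Monte-Carlo multinomial null (micelle size as draw count).

**Lamellar.**  The director is the principal axis of the second-moment
(nematic) tensor of molecular end-to-end unit vectors — robust to the
head/tail sign ambiguity, with an isotropy guard when the top
eigenvalues are degenerate within 1%.  The layer count κ is the
dominant harmonic of the surfactant density projected on the director
(period L cosθ); the peak must exceed both twice the median background
and an absolute noise floor of 25/N (the null power is Exp(1/N)).
Then d = L cosθ/κ.  The box admits only d = L/√(κ_x²+κ_y²+κ_z²) over
integer layer projections — the one-dimensional triangle construction
generalised to an arbitrary normal — and the catalog deduplicates at 3
significant figures.  The concentration model
d = d_s(N_sV_s + N_IV_I + N_wV_w)/(N_sV_s) is fit by least squares
with d_s the lone parameter; bead volumes default to
(4/3)π(R_ii^C/2)³ (the half-cutoff radius convention;
config-selectable).  Distinct water slabs for bridge counting: the
periodic identifications collapse the layer slices to gcd(κᵢ) distinct
slabs, and a frame with fewer macroscopic water clusters than that has
a bridge; stacks bridged in more than 5% of frames are classified
imperfect (the threshold is a package default, config-exposed).

**Hexagonal.**  The rod axis is the box axis whose transverse
projection of the tail density is most structured (highest 2D
histogram contrast); transverse tails are clustered periodically, and
elongated clusters (extent > L/4) reject the configuration as
non-hexagonal.  Because the rod lattice must tile the transverse cell
— integer combinations of a⃗, b⃗ generate both periodic images (L,0)
and (0,L) — the rod lattice is a superlattice of (L·Z)², and the rod
*count* fixes its index.  The fit therefore enumerates every
commensurate lattice of that index (Hermite normal forms, each lattice
once), scores each by how tightly the centres collapse onto one
lattice offset, and reports the Gauss-reduced basis of the best;
best-fit residuals above 0.5 r_C mark the arrangement incommensurate.
r_S = (|a⃗|+|b⃗|+|a⃗−b⃗|)/3.  Orientation is "parallel" when a
nearest-neighbour vector lies within 5° of the first transverse axis
(the shear plane) and "perpendicular" within 5° of the second.

The allowed-r_S catalog runs the same enumeration over all indices up
to the smallest near-hexagonal cell area in range, filters cells whose
three nearest-neighbour lengths differ pairwise by more than
d_co = 1.5 (three lengths rather than two because r_S averages three;
the choice is config-exposed), and deduplicates r_S at 3 significant
figures.  Mirror-image cells share all three lengths, so counting them
separately changes only a recorded cell count, never the value list.
For L = 40 this yields exactly 10 values in (7.5, 11), containing both
7.52 and the 9.65 of the axis-aligned |a⃗| = 10 cell; for L = 50 the
same pipeline yields 21 values.

**Phase classification** follows the percolation dimensionality of the
largest tail cluster (BFS image bookkeeping per dimension): 0 →
micellar; 1 → hexagonal if the rod-lattice fit succeeds and is
commensurate, else worm-like micellar; ≥2 → lamellar (perfect or
imperfect by bridge fraction), with "hexagonal/lamellar" when both
fits pass and "indeterminate" otherwise.

## Synthetic fixtures

The generators build geometric scaffolds with exact ground truth:
micelle fields (tails packed in density-matched spheres, heads on the
shell, counterions nearby, centres rejection-sampled with safe gaps),
lamellar stacks (molecules snapped to slab surfaces of a commensurate
tilted stack, optional per-frame water bridges through a slab), and
hexagonal rod lattices (radial chains in cylinders at the lattice
points).  All fill with water and ions to ρ = 3 and zero net charge,
and thermal disorder is emulated by seeded isotropic gaussian jitter.
They emulate geometry only — no thermodynamics, no realistic interface
widths, no chain conformational statistics — so passing round-trip
tests certifies the *analyses*, not the realism of the structures; the
simulation engine is validated separately by its property suite and
the self-assembly run.

## Problem sizes and numerical choices

Desk-scale defaults keep the full suite and the acceptance script to a
few minutes on one core: property checks use 200–3000 beads (L = 5 and
L = 10), thermostat calibration runs 10⁴ steps, the self-assembly run
uses 30 wt% SDS at L = 10 and stops as soon as aggregates exceed ten
molecules (well inside its 2×10⁵-step budget), and fixtures for the
mesophase analyses use L = 40.  The published phase-diagram boxes
(L up to 50, ≥2.5×10⁷ steps) use the same engine with larger
schedules.  Degenerate inputs are handled explicitly: coincident beads
receive the maximum repulsion along a seeded random direction (soft
potentials make overlap legal at initialisation), collinear angles use
the analytic sinθ → 0 limit, and catalog deduplication matches the
3-significant-figure precision at which spacings are conventionally
quoted.

## Known limitations

The shipped a_ij/R_ij^C matrices and bond-length rule are
reconstructed to the published alkyl-sulfate parameterisation scheme,
not transcribed from its original tables (see the note in
`data/forcefield.yaml`); quantitative phase-boundary work should
replace them.  The polydisperse ethoxylation weights are a smooth
choice matching the published mean (0.76) only.  Shape analysis stops
at R_G (no asphericity eigenvalue decomposition); temperature
dependence is out of scope (the parameterisation is 25 °C only); and
the smearing-correction image sum omits self-images, negligible for
boxes of edge ≥ 6 r_C.
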