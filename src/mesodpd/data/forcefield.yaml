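# Coarse-grained force field for SLE_nS (sodium lauryl ether sulfate) in
# water at 25 C.
#
# EDITABLE TRANSCRIPTION TARGET.  The pairwise (a_ij, R_ij^C) matrices
# and the bond-length rule follow the published alkyl-sulfate DPD
# parameterisation of Anderson et al. (J. Chem. Phys. 147, 094503 and
# follow-ups), in which both the repulsion and the cutoff vary per pair
# and the solvent-solvent cutoff R_WW = 1 defines the length unit.  The
# numeric entries below are RECONSTRUCTED to that scheme's rules
# (cutoffs from bead-volume scaling, a_ii = 25 baseline at reduced
# density 3, hydrophobic tail/water contrast driving self-assembly);
# replace them with the original published tables for quantitative
# comparisons.  Everything downstream is parametric in this file.
#
# Species: W = 2 H2O, C = 3-carbon alkyl segment (C12 tail = 4 beads),
# E = CH2OCH2 ethoxy unit, S = OSO3- sulfate head, Na = Na+.2H2O.

species: [W, C, E, S, Na]

beads:
  W:  {charge: 0,  molar_mass: 36.03, surfactant_mass: 0.0,  role: solvent}
  C:  {charge: 0,  molar_mass: 42.33, surfactant_mass: 42.33, heavy_atoms: 3, role: tail}
  E:  {charge: 0,  molar_mass: 44.05, surfactant_mass: 44.05, heavy_atoms: 3, role: ethoxy}
  S:  {charge: -1, molar_mass: 96.06, surfactant_mass: 96.06, heavy_atoms: 5, role: head}
  # hydrating waters on the counterion are counted as water mass
  Na: {charge: 1,  molar_mass: 59.03, surfactant_mass: 23.00, role: ion}

# Maximum repulsion a_ij (reduced energy / reduced length), order W C E S Na
repulsion:
  - [25.0, 45.0, 28.0, 22.0, 22.0]
  - [45.0, 25.0, 32.0, 45.0, 40.0]
  - [28.0, 32.0, 25.0, 26.0, 26.0]
  - [22.0, 45.0, 26.0, 25.0, 22.0]
  - [22.0, 40.0, 26.0, 22.0, 25.0]

# Pair cutoffs R_ij^C (reduced length); diagonal from bead-volume
# scaling, off-diagonal arithmetic means; R_WW = 1 exactly.
cutoff:
  - [1.000, 1.050, 1.010, 0.990, 1.025]
  - [1.050, 1.100, 1.060, 1.040, 1.075]
  - [1.010, 1.060, 1.020, 1.000, 1.035]
  - [0.990, 1.040, 1.000, 0.980, 1.015]
  - [1.025, 1.075, 1.035, 1.015, 1.050]

# Bead volume for the d-spacing model: radius = R_ii/2 ("half_cutoff")
# or R_ii ("cutoff"); config-selectable.
volume_convention: half_cutoff

bonded:
  spring_constant: 150.0
  angle_constant: 5.0
  equilibrium_angle: 180.0
  # l0 = coefficient * (heavy atoms in bead i + heavy atoms in bead j)
  bond_rule: {type: linear_heavy_atoms, coefficient: 0.1}

thermostat:
  sigma: 3.0
  kT: 1.0
  dt: 0.01

electrostatics:
  # coupling (Gamma) derived from the active unit map when omitted
  slater_beta: 0.929
  relative_permittivity: 78.3
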