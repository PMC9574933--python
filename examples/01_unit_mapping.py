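"""Map reduced DPD units to SI for room-temperature water.

One water bead stands for two H2O molecules and the reduced bead
density is 3; matching the coarse-grained mass density to liquid water
at 25 C fixes the length scale, and kT fixes the energy scale.
"""

from mesodpd import build_unit_map, convert, gamma_from_sigma

um = build_unit_map(temperature_kelvin=298.15, water_mass_density=997.0,
                    water_molecules_per_bead=2, reduced_density=3)

print(f"length scale r_C = {um.length_scale / 1e-10:.3f} angstrom")
print(f"time scale   tau = {um.time_scale:.4g} s")
print(f"time step 0.01 tau = {convert(0.01, (0, 0, 0, 1), 'to_si', um):.3g} s")
print(f"friction gamma = {gamma_from_sigma(3.0, 1.0)} (reduced) "
      f"= {convert(4.5, (0, 1, 0, -1), 'to_si', um):.3g} kg/s")
print(f"7.52 reduced lengths = "
      f"{convert(7.52, (1, 0, 0, 0), 'to_si', um) / 1e-9:.3f} nm")
# The length scale ~5.65 angstrom sets the physical size of every
# structure below; 7.52 reduced units is a typical hexagonal inter-rod
# spacing, i.e. about 4.25 nm between surfactant rods.
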