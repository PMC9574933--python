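"""Hexagonal inter-rod spacing and the finite-box spacing catalog.

Periodic boundaries force a rod lattice to tile the transverse L x L
cell, so only a discrete set of near-hexagonal cells is available.
The catalog enumerates them (pairwise nearest-neighbour length
differences at most d_co = 1.5), and the rod-detection + lattice-fit
pipeline recovers the generating cell of a synthetic phase.
"""

from mesodpd import (allowed_r_s, analyze_hexagonal, default_force_field,
                     make_hexagonal)

ff = default_force_field()

cat = allowed_r_s(40.0, d_co=1.5, r_min=7.5, r_max=11.0)
print(f"L=40 allows {len(cat)} average inter-rod spacings in (7.5, 11):")
print(" ", cat.values.tolist())

# the distorted cell with a = (10, 0), b = (4, 8): one lattice vector is
# axis-aligned with |a| = L/4, giving the three nearest-neighbour
# distances 10, sqrt(80), 10 and average r_S = 9.65
cfg, truth = make_hexagonal(40.0, a=[10, 0], b=[4, 8], noise_sigma=0.1,
                            seed=9, force_field=ff)
hm = analyze_hexagonal(cfg, tail_species=ff.tail_species())
print(f"\ngenerated r_S = {truth['r_s']:.3f}; recovered r_S = {hm.r_s:.3f}")
print(f"lattice vectors a={hm.a.round(3).tolist()}, "
      f"b={hm.b.round(3).tolist()}; orientation: {hm.orientation}")
print(f"commensurate with the box: {hm.commensurate}")
# "parallel" means a nearest-neighbour vector lies in the shear plane,
# the orientation sheared hexagonal phases prefer; every recovered r_S
# must be a member of the catalog above.
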