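"""Build a small SDS solution and evolve it with the DPD engine.

A 30 wt% sodium dodecyl sulfate (n = 0 ethoxy groups) box at L = 8 is
initialised randomly and run for a few thousand steps; the kinetic
temperature settles near the thermostat target kT = 1 and the
hydrophobic tails begin to aggregate.
"""

from mesodpd import (Schedule, build_slens, composition_from_weight_percent,
                     default_force_field, find_micelles,
                     random_initial_configuration, run)

ff = default_force_field()
top = build_slens(0, ff)
comp = composition_from_weight_percent(8.0, 30.0, {0: top}, ff)
print(f"box L={comp.box_edge}: {sum(comp.molecule_counts.values())} chains, "
      f"{comp.water_count} water beads "
      f"({comp.realized_weight_percent:.2f} wt% realised)")

cfg = random_initial_configuration(comp, seed=7)
frames = run(cfg, ff, Schedule(steps=4000, snapshot_stride=1000, seed=7))

for f in frames:
    ms = find_micelles(f, 1.0, ff.tail_species())
    largest = ms.sizes.max() if ms.n_micelles else 0
    print(f"t={f.time:7.1f}  kT={f.kinetic_temperature():.3f}  "
          f"clusters={ms.n_micelles:3d}  N_agg={ms.aggregation_number():6.2f}"
          f"  largest={largest}")
# N_agg (mean molecules per aggregate) grows from ~1 as free chains
# merge into micelles; the largest cluster exceeding ~10 molecules
# marks the onset of self-assembly.
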