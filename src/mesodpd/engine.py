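"""NVT evolution of DPD configurations, with optional Lees-Edwards shear.

Integration uses the modified velocity-Verlet scheme customary for DPD
(prediction parameter lambda = 0.65): forces are evaluated once per
step at the updated positions with predicted velocities, and reused as
the old force of the following step.  With the counter-based noise
stream, trajectories are bitwise reproducible for a fixed seed and a
checkpoint restart continues identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .electrostatics import electrostatic_forces
from .forcefield import ForceField
from .forces import BondTable, bond_table_from_molecules
from .system import Configuration

LAMBDA = 0.65


class EngineError(RuntimeError):
    """Integration failure; carries the last good checkpoint."""

    def __init__(self, message, checkpoint=None):
        super().__init__(message)
        self.checkpoint = checkpoint


@dataclass(frozen=True)
class Schedule:
    """Run settings: step count, snapshot stride and shear rate."""

    steps: int
    snapshot_stride: int = 100
    shear_rate: float = 0.0
    seed: int = 0


@dataclass
class Checkpoint:
    configuration: Configuration
    force_cache: np.ndarray | None
    step_index: int


class Simulation:
    """Stateful integrator bound to one configuration and force field."""

    def __init__(self, configuration: Configuration,
                 force_field: ForceField, seed: int = 0,
                 shear_rate: float = 0.0,
                 with_electrostatics: bool | None = None,
                 bond_table: BondTable | None = None):
        self.config = configuration.copy()
        self.config.shear_rate = shear_rate
        self.ff = force_field
        self.seed = int(seed)
        table = force_field.interactions
        self.types = self.config.species_indices(table.species)
        self.aij = np.ascontiguousarray(table.repulsion)
        self.rcij = np.ascontiguousarray(table.cutoff)
        self.max_cutoff = table.max_cutoff
        self.charges = np.array([force_field.charge_of(str(s))
                                 for s in self.config.species], dtype=float)
        if with_electrostatics is None:
            with_electrostatics = bool(np.any(self.charges))
        self.with_electrostatics = with_electrostatics and bool(
            np.any(self.charges))
        self.bonds = (bond_table if bond_table is not None
                      else bond_table_from_molecules(self.config, force_field))
        th = force_field.thermostat
        self.dt = th.dt
        self.sigma, self.gamma = th.sigma, th.gamma
        self.step_index = int(round(self.config.time / self.dt))
        self._force = None

    # -- force evaluation -------------------------------------------------
    def _forces(self, velocities: np.ndarray) -> np.ndarray:
        cfg = self.config
        n = len(cfg)
        f = np.zeros((n, 3))
        _kernels.nonbonded_forces_cells(
            cfg.positions, velocities, self.types, self.aij, self.rcij,
            cfg.box_edge, cfg.shear_offset, cfg.shear_rate,
            self.sigma, self.gamma, self.dt, self.seed, self.step_index,
            True, self.max_cutoff, f)
        if len(self.bonds.bond_i) or len(self.bonds.ang_i):
            _kernels.bonded_forces(
                cfg.positions, self.bonds.bond_i, self.bonds.bond_j,
                self.bonds.bond_l0, self.bonds.bond_c, self.bonds.ang_i,
                self.bonds.ang_j, self.bonds.ang_k, self.bonds.theta0,
                self.bonds.dconst, cfg.box_edge, cfg.shear_offset, f)
        if self.with_electrostatics:
            fe, _ = electrostatic_forces(cfg, self.charges,
                                         self.ff.electrostatics)
            f += fe
        return f

    # -- integration ------------------------------------------------------
    def step(self) -> Configuration:
        """Advance one time step (modified velocity-Verlet)."""
        cfg = self.config
        dt = self.dt
        if self._force is None:
            self._force = self._forces(cfg.velocities)
        f_old = self._force
        if not np.all(np.isfinite(f_old)):
            raise EngineError("non-finite forces encountered",
                              checkpoint=self.checkpoint())
        cfg.positions += dt * cfg.velocities + 0.5 * dt * dt * f_old
        v_pred = cfg.velocities + LAMBDA * dt * f_old
        # the boundary image offset advances with the shear flow
        if cfg.shear_rate != 0.0:
            cfg.shear_offset = (cfg.shear_offset
                                + cfg.shear_rate * cfg.box_edge * dt) \
                % cfg.box_edge
        cfg.wrap()
        self.step_index += 1
        f_new = self._forces(v_pred)
        cfg.velocities += 0.5 * dt * (f_old + f_new)
        self._force = f_new
        cfg.time = self.step_index * dt
        return cfg

    def checkpoint(self) -> Checkpoint:
        return Checkpoint(configuration=self.config.copy(),
                          force_cache=(None if self._force is None
                                       else self._force.copy()),
                          step_index=self.step_index)

    @classmethod
    def from_checkpoint(cls, chk: Checkpoint, force_field: ForceField,
                        seed: int = 0, **kwargs) -> "Simulation":
        sim = cls(chk.configuration, force_field, seed=seed,
                  shear_rate=chk.configuration.shear_rate, **kwargs)
        sim.step_index = chk.step_index
        sim._force = None if chk.force_cache is None else chk.force_cache.copy()
        return sim


def step(configuration: Configuration, force_field: ForceField,
         dt: float | None = None, seed: int = 0,
         shear_rate: float = 0.0) -> Configuration:
    """One integration step as a pure function (convenience wrapper)."""
    sim = Simulation(configuration, force_field, seed=seed,
                     shear_rate=shear_rate)
    if dt is not None and dt != sim.dt:
        raise ValueError("dt is fixed by the force field thermostat block")
    return sim.step().copy()


def run(configuration: Configuration, force_field: ForceField,
        schedule: Schedule,
        with_electrostatics: bool | None = None) -> list[Configuration]:
    """Evolve under a schedule, returning snapshots (t=0 included).

    A stride of s over n steps yields ``n // s + 1`` snapshots.  On
    non-finite forces the run aborts with the last good checkpoint in
    the raised :class:`EngineError`.
    """
    sim = Simulation(configuration, force_field, seed=schedule.seed,
                     shear_rate=schedule.shear_rate,
                     with_electrostatics=with_electrostatics)
    snapshots = [sim.config.copy()]
    for k in range(1, schedule.steps + 1):
        sim.step()
        if k % schedule.snapshot_stride == 0:
            snapshots.append(sim.config.copy())
    return snapshots


def apply_lees_edwards(configuration: Configuration, shear_rate: float,
                       dt: float) -> Configuration:
    """Advance the shear boundary offset and re-wrap the configuration.

    The image offset grows by ``shear_rate * L * dt`` (modulo L);
    particles crossing the y boundary acquire the image displacement
    and image-velocity correction.  With zero rate this reduces to a
    plain periodic wrap.
    """
    out = configuration.copy()
    out.shear_rate = shear_rate
    out.shear_offset = (out.shear_offset
                        + shear_rate * out.box_edge * dt) % out.box_edge
    out.wrap()
    return out


def kinetic_temperature_series(snapshots) -> np.ndarray:
    return np.array([s.kinetic_temperature() for s in snapshots])
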