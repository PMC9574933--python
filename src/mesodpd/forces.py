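"""Single-pair DPD force laws and whole-system force evaluation.

The pair forces follow the standard soft-repulsion DPD model: a linear
conservative repulsion ``a_ij (1 - r/R_ij^C)`` below a pair-specific
cutoff, and a dissipative/random pair acting as a momentum-conserving
thermostat with weight functions ``w_R(r) = 1 - r/R_ij^C`` and
``w_D = w_R^2`` linked by the fluctuation-dissipation relation
``sigma^2 = 2 gamma kT``.  Harmonic bonds and angle potentials
straighten the surfactant chains.

Whole-system evaluation offers two routes with identical per-pair
arithmetic: a brute-force O(N^2) sweep and a cell-list sweep; tests
assert their equality.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from . import _kernels
from .electrostatics import electrostatic_forces
from .forcefield import ForceField
from .system import Configuration, minimum_image


def conservative_force(r_ij_vector, a_ij: float, R_ij_cutoff: float,
                       rng_seed: int = 0) -> np.ndarray:
    """Soft repulsion on bead i from bead j.

    Magnitude ``a_ij (1 - r/R^C)`` directed from j to i, zero at and
    beyond the cutoff.  Coincident beads receive the maximum repulsion
    along a seeded random direction (overlap is legal for soft beads).
    """
    r_ij_vector = np.asarray(r_ij_vector, dtype=float)
    r = np.linalg.norm(r_ij_vector)
    if r >= R_ij_cutoff:
        return np.zeros(3)
    if r < 1e-12:
        rng = np.random.default_rng(rng_seed)
        u = rng.normal(size=3)
        return a_ij * u / np.linalg.norm(u)
    return a_ij * (1.0 - r / R_ij_cutoff) * r_ij_vector / r


def pair_thermostat_forces(r_ij_vector, v_ij_vector, gamma: float,
                           sigma: float, R_ij_cutoff: float, dt: float,
                           noise: float) -> tuple[np.ndarray, np.ndarray]:
    """Dissipative and random forces on bead i for one pair.

    ``noise`` is the symmetric unit normal draw zeta_ij.  The random
    force scales as ``dt^(-1/2)`` so that the impulse per step has the
    correct variance.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    r_ij_vector = np.asarray(r_ij_vector, dtype=float)
    v_ij_vector = np.asarray(v_ij_vector, dtype=float)
    r = np.linalg.norm(r_ij_vector)
    if r >= R_ij_cutoff or r < 1e-12:
        return np.zeros(3), np.zeros(3)
    rhat = r_ij_vector / r
    w = 1.0 - r / R_ij_cutoff
    dissipative = -gamma * w * w * float(rhat @ v_ij_vector) * rhat
    random = sigma * w * noise / math.sqrt(dt) * rhat
    return dissipative, random


def bond_force(r_ij: float, l_0: float, C: float) -> tuple[float, float]:
    """(force on i along r_hat, potential energy) for a harmonic bond.

    ``U = (C/2)(r - l0)^2``; the force restores toward ``l0`` and the
    returned pair is antisymmetric between partners by convention.
    """
    if l_0 <= 0 or C <= 0:
        raise ValueError("l_0 and C must be > 0")
    return -C * (r_ij - l_0), 0.5 * C * (r_ij - l_0) ** 2


def angle_force(pos_i, pos_j, pos_k, theta_0: float, D: float
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forces on the (i, j, k) triple from ``U = (D/2)(theta - theta_0)^2``.

    ``theta_0`` in degrees; ``j`` is the vertex.  Net force and net
    torque vanish; the collinear configuration at theta = theta_0 is
    handled by the analytic limit (zero force).
    """
    b1 = np.asarray(pos_i, float) - np.asarray(pos_j, float)
    b2 = np.asarray(pos_k, float) - np.asarray(pos_j, float)
    r1 = np.linalg.norm(b1)
    r2 = np.linalg.norm(b2)
    if r1 < 1e-12 or r2 < 1e-12:
        raise ValueError("angle bond vectors must be nonzero")
    u1, u2 = b1 / r1, b2 / r2
    cost = float(np.clip(u1 @ u2, -1.0, 1.0))
    theta = math.acos(cost)
    sint = math.sqrt(max(1.0 - cost * cost, 1e-16))
    coef = D * (theta - math.radians(theta_0)) / sint
    f_i = (coef / r1) * (u2 - cost * u1)
    f_k = (coef / r2) * (u1 - cost * u2)
    return f_i, -(f_i + f_k), f_k


def angle_energy(pos_i, pos_j, pos_k, theta_0: float, D: float) -> float:
    b1 = np.asarray(pos_i, float) - np.asarray(pos_j, float)
    b2 = np.asarray(pos_k, float) - np.asarray(pos_j, float)
    cost = float(np.clip(b1 @ b2 / (np.linalg.norm(b1) * np.linalg.norm(b2)),
                         -1.0, 1.0))
    return 0.5 * D * (math.acos(cost) - math.radians(theta_0)) ** 2


@dataclass
class BondTable:
    """Flat bond/angle arrays for kernel consumption."""

    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_l0: np.ndarray
    bond_c: np.ndarray
    ang_i: np.ndarray
    ang_j: np.ndarray
    ang_k: np.ndarray
    theta0: np.ndarray   # radians
    dconst: np.ndarray

    @classmethod
    def empty(cls) -> "BondTable":
        z = np.zeros(0, dtype=np.int64)
        f = np.zeros(0)
        return cls(z, z, f, f, z, z, z, f, f)


def bond_table_from_molecules(configuration: Configuration,
                              force_field: ForceField) -> BondTable:
    """Infer chain bonds/angles from contiguous molecule blocks.

    Builders in this package lay molecules out contiguously in bead
    order; consecutive beads of a multi-bead molecule are bonded, and
    every interior bead carries one angle triple.
    """
    mol = configuration.molecule_id
    species = configuration.species
    bp = force_field.bonded
    bi, bj, bl, bc = [], [], [], []
    ai, aj, ak = [], [], []
    start = 0
    n = len(mol)
    while start < n:
        end = start
        while end + 1 < n and mol[end + 1] == mol[start]:
            end += 1
        for p in range(start, end):
            bi.append(p)
            bj.append(p + 1)
            bl.append(bp.bond_length(str(species[p]), str(species[p + 1])))
            bc.append(bp.spring_constant)
        for p in range(start + 1, end):
            ai.append(p - 1)
            aj.append(p)
            ak.append(p + 1)
        start = end + 1
    nang = len(ai)
    return BondTable(
        np.array(bi, dtype=np.int64), np.array(bj, dtype=np.int64),
        np.array(bl, float), np.array(bc, float),
        np.array(ai, dtype=np.int64), np.array(aj, dtype=np.int64),
        np.array(ak, dtype=np.int64),
        np.full(nang, math.radians(bp.equilibrium_angle)),
        np.full(nang, bp.angle_constant))


@dataclass
class ForceBreakdown:
    """Per-bead force components; pairwise parts are antisymmetric."""

    conservative_dissipative_random: np.ndarray
    bond_angle: np.ndarray
    electrostatic: np.ndarray
    electrostatic_energy: float = 0.0

    @property
    def total(self) -> np.ndarray:
        return (self.conservative_dissipative_random + self.bond_angle
                + self.electrostatic)


def compute_forces(configuration: Configuration,
                   force_field: ForceField,
                   bond_table: BondTable | None = None,
                   charges: np.ndarray | None = None,
                   seed: int = 0, step: int = 0,
                   use_thermostat: bool = True,
                   method: str = "cells",
                   with_electrostatics: bool | None = None
                   ) -> ForceBreakdown:
    """Evaluate all forces on a configuration.

    ``method`` selects the ``"cells"`` or ``"brute"`` nonbonded sweep
    (identical pair arithmetic, used as a cross-check).  Electrostatics
    default to on whenever any bead carries charge.
    """
    table = force_field.interactions
    types = configuration.species_indices(table.species)
    th = force_field.thermostat
    n = len(configuration)
    f_nb = np.zeros((n, 3))
    args = (configuration.positions, configuration.velocities, types,
            table.repulsion, table.cutoff, configuration.box_edge,
            configuration.shear_offset, configuration.shear_rate,
            th.sigma, th.gamma, th.dt, seed, step, use_thermostat)
    if method == "brute":
        _kernels.nonbonded_forces_brute(*args, f_nb)
    elif method == "cells":
        _kernels.nonbonded_forces_cells(*args, table.max_cutoff, f_nb)
    else:
        raise ValueError(f"unknown method {method!r}")

    f_bond = np.zeros((n, 3))
    if bond_table is None:
        bond_table = bond_table_from_molecules(configuration, force_field)
    if len(bond_table.bond_i) or len(bond_table.ang_i):
        _kernels.bonded_forces(
            configuration.positions,
            bond_table.bond_i, bond_table.bond_j, bond_table.bond_l0,
            bond_table.bond_c, bond_table.ang_i, bond_table.ang_j,
            bond_table.ang_k, bond_table.theta0, bond_table.dconst,
            configuration.box_edge, configuration.shear_offset, f_bond)

    if charges is None:
        charges = np.array([force_field.charge_of(str(s))
                            for s in configuration.species], dtype=float)
    f_el = np.zeros((n, 3))
    e_el = 0.0
    if with_electrostatics is None:
        with_electrostatics = bool(np.any(charges))
    if with_electrostatics and np.any(charges):
        f_el, e_el = electrostatic_forces(configuration, charges,
                                          force_field.electrostatics)
    return ForceBreakdown(conservative_dissipative_random=f_nb,
                          bond_angle=f_bond, electrostatic=f_el,
                          electrostatic_energy=e_el)
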