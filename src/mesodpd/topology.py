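"""Molecule construction, ethoxylation sampling and box composition.

An SLE_nS chain is a linear sequence ``C-C-C-C-(E)*n-S`` carrying net
charge -1, balanced by one free hydrated sodium bead.  Commercial AES
products are polydisperse in the ethoxylation number n; the shipped
default distribution over n = 0..3 has mean 0.76, matching the
simplified representation of a commercial AES paste.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import ForceField
from .system import Configuration


@dataclass(frozen=True)
class MoleculeTopology:
    """One surfactant chain: ordered beads, bonds and angle triples."""

    bead_sequence: tuple[str, ...]
    bonds: tuple[tuple[int, int, float, float], ...]   # (i, j, l0, C)
    angles: tuple[tuple[int, int, int, float, float], ...]  # (i,j,k, theta0, D)
    ethoxylation: int
    net_charge: int

    def __post_init__(self) -> None:
        nb = len(self.bead_sequence)
        for i, j, l0, _ in self.bonds:
            if j != i + 1:
                raise ValueError("bonds must connect adjacent sequence positions")
            if l0 <= 0:
                raise ValueError("bond l0 must be > 0")
        interior = {j for _, j, _, _, _ in self.angles}
        expected = set(range(1, nb - 1))
        if interior != expected:
            raise ValueError("every interior bead must appear in exactly one "
                             "angle triple")

    @property
    def n_beads(self) -> int:
        return len(self.bead_sequence)


def build_slens(n: int, force_field: ForceField,
                tail_beads: int = 4) -> MoleculeTopology:
    """Build an SLE_nS chain with ``n`` ethoxy beads.

    The C12 tail is four 3-carbon beads; ``n`` ethoxy beads sit between
    the tail and the sulfate head.  Bond lengths follow the force
    field's heavy-atom rule and every consecutive triple carries a
    straightening angle potential.
    """
    if n < 0:
        raise ValueError(f"ethoxylation n must be >= 0, got {n}")
    seq = ("C",) * tail_beads + ("E",) * n + ("S",)
    bp = force_field.bonded
    bonds = tuple(
        (i, i + 1, bp.bond_length(seq[i], seq[i + 1]), bp.spring_constant)
        for i in range(len(seq) - 1))
    angles = tuple(
        (i - 1, i, i + 1, bp.equilibrium_angle, bp.angle_constant)
        for i in range(1, len(seq) - 1))
    charge = sum(force_field.charge_of(s) for s in seq)
    return MoleculeTopology(bead_sequence=seq, bonds=bonds, angles=angles,
                            ethoxylation=n, net_charge=charge)


@dataclass(frozen=True)
class EthoxylationDistribution:
    """Discrete distribution of the ethoxylation number n."""

    weights: dict[int, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")

    @property
    def support(self) -> tuple[int, ...]:
        return tuple(sorted(self.weights))

    @property
    def mean(self) -> float:
        return sum(n * w for n, w in self.weights.items())


def default_aes_distribution() -> EthoxylationDistribution:
    """Simplified commercial AES ethoxylation distribution (mean 0.76).

    Only the mean of the product distribution is published for the
    simplified n = 0..3 representation; the weights here are a smooth
    decreasing choice achieving that mean and are config-overridable.
    """
    return EthoxylationDistribution({0: 0.52, 1: 0.28, 2: 0.12, 3: 0.08})


def sample_ethoxylation(distribution: EthoxylationDistribution,
                        n_molecules: int, seed: int) -> dict[int, int]:
    """Multinomial draw of per-n molecule counts (deterministic per seed)."""
    if n_molecules <= 0:
        raise ValueError("n_molecules must be > 0")
    rng = np.random.default_rng(seed)
    support = distribution.support
    probs = np.array([distribution.weights[n] for n in support])
    counts = rng.multinomial(n_molecules, probs)
    return {n: int(c) for n, c in zip(support, counts)}


@dataclass(frozen=True)
class SystemComposition:
    """Bead budget of one simulation box at reduced density 3."""

    box_edge: float
    weight_percent: float
    realized_weight_percent: float
    molecule_counts: dict[int, int]          # ethoxylation n -> chain count
    topologies: dict[int, MoleculeTopology] = field(repr=False, default=None)
    water_count: int = 0
    sodium_count: int = 0
    total_bead_count: int = 0

    def __post_init__(self) -> None:
        chains = sum(self.molecule_counts.values())
        if self.sodium_count != chains:
            raise ValueError("one sodium bead is required per chain")
        beads = sum(c * self.topologies[n].n_beads
                    for n, c in self.molecule_counts.items())
        if beads + self.sodium_count + self.water_count != self.total_bead_count:
            raise ValueError("bead budget does not close")

    @property
    def net_charge(self) -> int:
        return (sum(c * self.topologies[n].net_charge
                    for n, c in self.molecule_counts.items())
                + self.sodium_count)


WATER_BEAD_MASS = 36.03  # g/mol represented by one water bead (2 H2O)


def _chain_surfactant_mass(top: MoleculeTopology, ff: ForceField) -> float:
    """Surfactant mass per chain incl. the bare Na of its counterion."""
    m = sum(ff.beads[s].surfactant_mass for s in top.bead_sequence)
    return m + ff.beads["Na"].surfactant_mass


def composition_from_weight_percent(
        L: float, weight_percent: float,
        topologies: dict[int, MoleculeTopology],
        force_field: ForceField,
        fractions: dict[int, float] | None = None,
        reduced_density: float = 3.0) -> SystemComposition:
    """Solve the bead budget for a target surfactant weight percentage.

    Weight percent is on an as-is molecular basis: the chain plus the
    bare sodium counts as surfactant, the counterion's hydrating waters
    count as water.  The total bead count is ``round(rho * L^3)`` with
    one sodium per chain and water filling the remainder.
    """
    if not (0 <= weight_percent < 100):
        raise ValueError("weight_percent must lie in [0, 100)")
    total_beads = int(round(reduced_density * L ** 3))
    if weight_percent == 0 or not topologies:
        return SystemComposition(
            box_edge=L, weight_percent=weight_percent,
            realized_weight_percent=0.0, molecule_counts={},
            topologies={}, water_count=total_beads, sodium_count=0,
            total_bead_count=total_beads)

    keys = sorted(topologies)
    if fractions is None:
        fractions = {k: 1.0 / len(keys) for k in keys}
    fsum = sum(fractions.get(k, 0.0) for k in keys)
    fr = {k: fractions.get(k, 0.0) / fsum for k in keys}

    w = weight_percent / 100.0
    mw = WATER_BEAD_MASS
    # per-chain means over the topology mixture
    mbar = sum(fr[k] * _chain_surfactant_mass(topologies[k], force_field)
               for k in keys)
    bbar = sum(fr[k] * (topologies[k].n_beads + 1) for k in keys)  # + Na bead
    n_chain = w * mw * total_beads / (mbar * (1 - w) + w * mw * (bbar - 1))
    n_chain = int(round(n_chain))
    if n_chain < 1:
        raise ValueError(
            f"box L={L} too small to hold one molecule at {weight_percent}%")

    # largest-remainder apportioning of chains over topologies
    raw = {k: fr[k] * n_chain for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    short = n_chain - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    counts = {k: c for k, c in counts.items() if c > 0}

    used = sum(c * (topologies[k].n_beads + 1) for k, c in counts.items())
    water = total_beads - used
    if water < 0:
        raise ValueError(
            f"box L={L} cannot hold {weight_percent}% surfactant: "
            f"{used} beads exceed the budget of {total_beads}")

    surf_mass = sum(c * _chain_surfactant_mass(topologies[k], force_field)
                    for k, c in counts.items())
    water_mass = mw * (water + sum(counts.values()))  # incl. hydrating waters
    realized = 100.0 * surf_mass / (surf_mass + water_mass)
    return SystemComposition(
        box_edge=L, weight_percent=weight_percent,
        realized_weight_percent=realized,
        molecule_counts=counts,
        topologies={k: topologies[k] for k in counts},
        water_count=water, sodium_count=sum(counts.values()),
        total_bead_count=total_beads)


def random_initial_configuration(composition: SystemComposition,
                                 seed: int,
                                 kT: float = 1.0) -> Configuration:
    """Random starting configuration for a composition.

    Chain beads are laid down as free random walks at the bonded
    separations (soft potentials tolerate the resulting overlaps);
    water and ions are uniform.  Velocities are Maxwellian at ``kT``
    with the total momentum removed.
    """
    rng = np.random.default_rng(seed)
    L = composition.box_edge
    species: list[str] = []
    mol: list[int] = []
    pos_blocks: list[np.ndarray] = []
    mol_counter = 0

    for n in sorted(composition.molecule_counts):
        top = composition.topologies[n]
        l0s = [b[2] for b in top.bonds]
        for _ in range(composition.molecule_counts[n]):
            p = np.empty((top.n_beads, 3))
            p[0] = rng.uniform(0, L, 3)
            for k, l0 in enumerate(l0s):
                step = rng.normal(size=3)
                step *= l0 / np.linalg.norm(step)
                p[k + 1] = p[k] + step
            pos_blocks.append(p)
            species.extend(top.bead_sequence)
            mol.extend([mol_counter] * top.n_beads)
            mol_counter += 1
    for _ in range(composition.sodium_count):
        pos_blocks.append(rng.uniform(0, L, (1, 3)))
        species.append("Na")
        mol.append(mol_counter)
        mol_counter += 1
    if composition.water_count:
        pos_blocks.append(rng.uniform(0, L, (composition.water_count, 3)))
        species.extend(["W"] * composition.water_count)
        mol.extend(range(mol_counter, mol_counter + composition.water_count))

    positions = (np.vstack(pos_blocks) if pos_blocks
                 else np.empty((0, 3)))
    n_total = len(positions)
    velocities = rng.normal(scale=np.sqrt(kT), size=(n_total, 3))
    if n_total:
        velocities -= velocities.mean(axis=0)
    return Configuration(
        positions=positions, velocities=velocities,
        species=np.array(species, dtype="<U2"),
        molecule_id=np.array(mol, dtype=np.int64),
        box_edge=L)
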