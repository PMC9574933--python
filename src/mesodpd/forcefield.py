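"""Force-field registry: bead species, interaction matrices, bonded terms.

The coarse-grained model describes sodium lauryl ether sulfate
(SLE_nS) in water with five bead species:

====== =============================== ======= ==============
label  chemistry                       charge  role
====== =============================== ======= ==============
W      2 H2O                            0      solvent
C      3 alkyl carbons (C12 tail = 4C)  0      tail
E      CH2OCH2 ethoxy unit              0      spacer
S      OSO3- sulfate head              -1      head
Na     Na+ . 2 H2O (hydrated ion)      +1      counterion
====== =============================== ======= ==============

Both the maximum repulsion ``a_ij`` and the pair cutoff ``R_ij^C`` vary
per species pair, with the solvent-solvent cutoff fixed at
``R_WW^C = 1`` defining the reduced length unit.  The shipped default
parameter file (``data/forcefield.yaml``) is an editable transcription
target for the published alkyl-sulfate parameterisation of Anderson and
co-workers; the numeric entries in it are reconstructed to that scheme's
volume-scaling rules and every operation in this package is parametric
in the table, so replacing the file recalibrates the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
import math

import numpy as np
import yaml

from .units import (ELEMENTARY_CHARGE, VACUUM_PERMITTIVITY, BOLTZMANN,
                    UnitMap, default_unit_map)


class ForceFieldError(ValueError):
    """Raised when a parameter document violates the model invariants."""


@dataclass(frozen=True)
class BeadSpec:
    """Per-species constants.

    ``molar_mass`` is the full chemical mass represented by the bead in
    g/mol; ``surfactant_mass`` is the portion counted as surfactant for
    weight-percent accounting (hydrating waters on the counterion count
    as water).  ``volume`` is the reduced bead volume used by the
    lamellar d-spacing model.
    """

    name: str
    mass: float
    charge: int
    self_cutoff: float
    volume: float
    molar_mass: float
    surfactant_mass: float
    heavy_atoms: int | None = None
    role: str = "solvent"

    def __post_init__(self) -> None:
        if self.mass != 1:
            raise ForceFieldError(f"bead {self.name}: reduced mass must be 1")
        if self.charge not in (-1, 0, 1):
            raise ForceFieldError(f"bead {self.name}: charge must be -1, 0 or +1")
        if self.self_cutoff <= 0:
            raise ForceFieldError(f"bead {self.name}: self_cutoff must be > 0")
        if self.volume <= 0:
            raise ForceFieldError(f"bead {self.name}: volume must be > 0")


@dataclass(frozen=True)
class InteractionTable:
    """Symmetric pairwise repulsion and cutoff matrices.

    Row/column order follows ``species``; the water-water cutoff is the
    unit of length and must be exactly 1.
    """

    species: tuple[str, ...]
    repulsion: np.ndarray
    cutoff: np.ndarray

    def __post_init__(self) -> None:
        errors = validate_interaction_table(self.species, self.repulsion,
                                            self.cutoff)
        if errors:
            raise ForceFieldError("; ".join(errors))

    def index(self, name: str) -> int:
        return self.species.index(name)

    def a(self, i: str, j: str) -> float:
        return float(self.repulsion[self.index(i), self.index(j)])

    def rc(self, i: str, j: str) -> float:
        return float(self.cutoff[self.index(i), self.index(j)])

    @property
    def max_cutoff(self) -> float:
        return float(self.cutoff.max())


def validate_interaction_table(species, repulsion, cutoff) -> list[str]:
    errors: list[str] = []
    n = len(species)
    for name, mat in (("repulsion", repulsion), ("cutoff", cutoff)):
        if mat.shape != (n, n):
            errors.append(f"{name} matrix must be {n}x{n}")
            continue
        for i in range(n):
            for j in range(i + 1, n):
                if not math.isclose(mat[i, j], mat[j, i], rel_tol=0, abs_tol=1e-12):
                    errors.append(
                        f"{name} matrix asymmetric for pair "
                        f"({species[i]}, {species[j]}): "
                        f"{mat[i, j]} != {mat[j, i]}")
    if cutoff.shape == (n, n):
        if np.any(cutoff <= 0):
            errors.append("all cutoffs must be > 0")
        if "W" in species:
            iw = species.index("W")
            if cutoff[iw, iw] != 1.0:
                errors.append(
                    f"water-water cutoff must be exactly 1, got {cutoff[iw, iw]}")
    return errors


@dataclass(frozen=True)
class ThermostatParams:
    """DPD thermostat amplitudes; sigma^2 = 2 * gamma * kT is enforced."""

    sigma: float
    gamma: float
    kT: float = 1.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ForceFieldError(f"dt must be > 0, got {self.dt}")
        if self.kT <= 0:
            raise ForceFieldError(f"kT must be > 0, got {self.kT}")
        if not math.isclose(self.sigma ** 2, 2 * self.gamma * self.kT,
                            rel_tol=1e-10, abs_tol=1e-12):
            raise ForceFieldError(
                f"fluctuation-dissipation violated: sigma^2={self.sigma**2} "
                f"!= 2*gamma*kT={2 * self.gamma * self.kT}")


@dataclass(frozen=True)
class ElectrostaticsParams:
    """Slater-smeared electrostatics with Ewald solver settings.

    ``coupling`` is the dimensionless Bjerrum-style parameter
    Gamma = e^2 / (k_B T eps0 eps_r r_C); ``slater_beta`` the inverse
    decay length of the exponential charge cloud (reduced units).
    Solver settings of ``None`` are auto-tuned at evaluation time to a
    ~1e-4 relative force accuracy.
    """

    coupling: float
    slater_beta: float = 0.929
    relative_permittivity: float = 78.3
    alpha: float | None = None
    kmax: int | None = None
    real_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.slater_beta <= 0:
            raise ForceFieldError("slater_beta must be > 0")
        if self.coupling <= 0:
            raise ForceFieldError("coupling must be > 0")


def coupling_from_unit_map(unit_map: UnitMap,
                           relative_permittivity: float = 78.3) -> float:
    """Electrostatic coupling Gamma = e^2/(k_B T eps0 eps_r r_C)."""
    return (ELEMENTARY_CHARGE ** 2
            / (unit_map.energy_scale * VACUUM_PERMITTIVITY
               * relative_permittivity * unit_map.length_scale))


@dataclass(frozen=True)
class BondedParams:
    """Harmonic bond/angle constants and the bond-length rule.

    The unstretched bond length between two chain beads grows with the
    number of heavy atoms (C, O, S) the beads represent.  The default
    rule is linear, ``l0 = coefficient * (n_i + n_j)``; an explicit
    per-pair table may override it.
    """

    spring_constant: float = 150.0
    angle_constant: float = 5.0
    equilibrium_angle: float = 180.0
    heavy_atom_counts: dict[str, int] = field(default_factory=dict)
    bond_rule: dict = field(default_factory=lambda: {
        "type": "linear_heavy_atoms", "coefficient": 0.1})

    def __post_init__(self) -> None:
        for name, n in self.heavy_atom_counts.items():
            if n < 1:
                raise ForceFieldError(
                    f"heavy_atom_counts[{name}] must be >= 1 for chain beads")

    def bond_length(self, species_i: str, species_j: str) -> float:
        rule = self.bond_rule
        if rule.get("type") == "pair_table":
            table = rule["table"]
            key = "-".join(sorted((species_i, species_j)))
            if key not in table:
                raise KeyError(
                    f"no bond-length entry for bead pair ({species_i}, {species_j})")
            return float(table[key])
        for s in (species_i, species_j):
            if s not in self.heavy_atom_counts:
                raise KeyError(
                    f"no heavy-atom count for bead pair ({species_i}, {species_j}):"
                    f" species {s} missing")
        return bond_length(self.heavy_atom_counts[species_i],
                           self.heavy_atom_counts[species_j], rule)


def bond_length(heavy_i: int, heavy_j: int, bond_rule: dict) -> float:
    """Unstretched bond length from heavy-atom counts.

    Symmetric in its arguments and (for the linear rule) monotone
    non-decreasing in ``heavy_i + heavy_j``.
    """
    if heavy_i < 1 or heavy_j < 1:
        raise ValueError("heavy-atom counts must be >= 1")
    kind = bond_rule.get("type", "linear_heavy_atoms")
    if kind == "linear_heavy_atoms":
        l0 = bond_rule.get("coefficient", 0.1) * (heavy_i + heavy_j)
    elif kind == "count_table":
        table = bond_rule["table"]
        key = tuple(sorted((heavy_i, heavy_j)))
        skey = f"{key[0]}-{key[1]}"
        if skey not in table:
            raise KeyError(f"no bond-length entry for heavy-atom pair {skey}")
        l0 = float(table[skey])
    else:
        raise ValueError(f"unknown bond rule type {kind!r}")
    if l0 <= 0:
        raise ValueError(f"bond rule produced non-positive l0={l0}")
    return l0


@dataclass(frozen=True)
class ForceField:
    """Validated parameter bundle for one simulation."""

    beads: dict[str, BeadSpec]
    interactions: InteractionTable
    bonded: BondedParams
    electrostatics: ElectrostaticsParams
    thermostat: ThermostatParams
    volume_convention: str = "half_cutoff"

    @property
    def species(self) -> tuple[str, ...]:
        return self.interactions.species

    def charge_of(self, name: str) -> int:
        return self.beads[name].charge

    def bead_volume(self, name: str) -> float:
        return self.beads[name].volume

    def tail_species(self) -> set[str]:
        return {n for n, b in self.beads.items() if b.role == "tail"}


def bead_volume_from_cutoff(self_cutoff: float, convention: str) -> float:
    """Reduced bead volume from the self cutoff.

    ``half_cutoff`` treats R_ii/2 as the bead radius (beads at the
    cutoff just touch); ``cutoff`` treats R_ii itself as the radius.
    """
    if convention == "half_cutoff":
        r = self_cutoff / 2.0
    elif convention == "cutoff":
        r = self_cutoff
    else:
        raise ForceFieldError(f"unknown volume convention {convention!r}")
    return 4.0 / 3.0 * math.pi * r ** 3


def load_force_field(config_document,
                     unit_map: UnitMap | None = None) -> ForceField:
    """Parse and validate a force-field document.

    ``config_document`` is a path to a YAML file or an already-parsed
    mapping.  All invariant violations are collected and reported in a
    single :class:`ForceFieldError`.  When ``coupling`` is absent the
    electrostatic coupling is derived from ``unit_map`` (default: the
    room-temperature water mapping).
    """
    if isinstance(config_document, (str,)) or hasattr(config_document, "read_text"):
        with open(config_document) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = config_document
    errors: list[str] = []

    species = tuple(doc["species"])
    n = len(species)
    rep = np.array(doc["repulsion"], dtype=float)
    cut = np.array(doc["cutoff"], dtype=float)
    errors.extend(validate_interaction_table(species, rep, cut))

    convention = doc.get("volume_convention", "half_cutoff")
    beads: dict[str, BeadSpec] = {}
    for i, name in enumerate(species):
        bdoc = doc["beads"][name]
        try:
            self_cut = float(cut[i, i]) if cut.shape == (n, n) else 1.0
            beads[name] = BeadSpec(
                name=name,
                mass=bdoc.get("mass", 1),
                charge=bdoc.get("charge", 0),
                self_cutoff=self_cut,
                volume=bdoc.get("volume",
                                bead_volume_from_cutoff(self_cut, convention)),
                molar_mass=bdoc["molar_mass"],
                surfactant_mass=bdoc.get("surfactant_mass", 0.0),
                heavy_atoms=bdoc.get("heavy_atoms"),
                role=bdoc.get("role", "solvent"),
            )
        except ForceFieldError as exc:
            errors.append(str(exc))

    tdoc = doc.get("thermostat", {})
    sigma = tdoc.get("sigma", 3.0)
    gamma = tdoc.get("gamma", None)
    kT = tdoc.get("kT", 1.0)
    if gamma is None:
        gamma = sigma ** 2 / (2 * kT)
    thermostat = None
    try:
        thermostat = ThermostatParams(sigma=sigma, gamma=gamma, kT=kT,
                                      dt=tdoc.get("dt", 0.01))
    except ForceFieldError as exc:
        errors.append(str(exc))

    bdoc = doc.get("bonded", {})
    heavy = {name: beads[name].heavy_atoms for name in species
             if name in beads and beads[name].heavy_atoms is not None}
    bonded = None
    try:
        bonded = BondedParams(
            spring_constant=bdoc.get("spring_constant", 150.0),
            angle_constant=bdoc.get("angle_constant", 5.0),
            equilibrium_angle=bdoc.get("equilibrium_angle", 180.0),
            heavy_atom_counts=heavy,
            bond_rule=bdoc.get("bond_rule",
                               {"type": "linear_heavy_atoms", "coefficient": 0.1}),
        )
    except ForceFieldError as exc:
        errors.append(str(exc))

    edoc = doc.get("electrostatics", {})
    eps_r = edoc.get("relative_permittivity", 78.3)
    coupling = edoc.get("coupling")
    if coupling is None:
        um = unit_map if unit_map is not None else default_unit_map()
        coupling = coupling_from_unit_map(um, eps_r)
    elif unit_map is not None:
        expected = coupling_from_unit_map(unit_map, eps_r)
        if not math.isclose(coupling, expected, rel_tol=1e-2):
            errors.append(
                f"electrostatic coupling {coupling} inconsistent with unit map "
                f"(expected {expected:.4g})")
    electro = None
    try:
        electro = ElectrostaticsParams(
            coupling=coupling,
            slater_beta=edoc.get("slater_beta", 0.929),
            relative_permittivity=eps_r,
            alpha=edoc.get("alpha"),
            kmax=edoc.get("kmax"),
            real_cutoff=edoc.get("real_cutoff"),
        )
    except ForceFieldError as exc:
        errors.append(str(exc))

    if errors:
        raise ForceFieldError("force-field document invalid: "
                              + "; ".join(errors))

    try:
        table = InteractionTable(species=species, repulsion=rep, cutoff=cut)
    except ForceFieldError as exc:  # pragma: no cover - already collected
        raise ForceFieldError(str(exc))

    return ForceField(beads=beads, interactions=table, bonded=bonded,
                      electrostatics=electro, thermostat=thermostat,
                      volume_convention=convention)


def default_force_field(unit_map: UnitMap | None = None) -> ForceField:
    """Load the packaged SLE_nS parameter file."""
    ref = resources.files("mesodpd").joinpath("data/forcefield.yaml")
    with resources.as_file(ref) as path:
        return load_force_field(path, unit_map=unit_map)
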