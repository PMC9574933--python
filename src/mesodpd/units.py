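"""Reduced-unit system and mapping to SI.

DPD simulations here use reduced units: the solvent-solvent cutoff sets
the length scale r_C, the bead mass sets the mass scale, and k_B*T sets
the energy scale.  The mapping to physical units follows the standard
water-density matching procedure: one water bead represents a fixed
number of water molecules, and the reduced bead number density is chosen
so that the mass density of the coarse-grained water equals the
experimental density of liquid water.  The derived time scale is
``tau = r_C * sqrt(m / k_B T)``.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

# CODATA / standard reference constants
BOLTZMANN = 1.380649e-23          # J/K
AVOGADRO = 6.02214076e23          # 1/mol
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
WATER_MOLAR_MASS = 18.015e-3      # kg/mol
ANGSTROM = 1e-10

#: exponent order used in dimension signatures: (length, mass, energy, time)
DIMENSION_ORDER = ("length", "mass", "energy", "time")


@dataclass(frozen=True)
class UnitMap:
    """Conversion factors from reduced to SI units.

    Attributes
    ----------
    length_scale : float
        Metres per reduced length (r_C).
    mass_scale : float
        Kilograms per reduced mass.
    energy_scale : float
        Joules per reduced energy (k_B T).
    time_scale : float
        Seconds per reduced time; always equal to
        ``length_scale * sqrt(mass_scale / energy_scale)``.
    """

    length_scale: float
    mass_scale: float
    energy_scale: float

    def __post_init__(self) -> None:
        for name in ("length_scale", "mass_scale", "energy_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def time_scale(self) -> float:
        return self.length_scale * math.sqrt(self.mass_scale / self.energy_scale)

    def scale_for(self, signature: tuple[int, int, int, int]) -> float:
        """Combined SI factor for a dimension signature ``(L, M, E, T)``."""
        if len(signature) != 4:
            raise ValueError(
                "dimension signature must be a 4-tuple of integer exponents "
                f"over {DIMENSION_ORDER}"
            )
        scales = (self.length_scale, self.mass_scale,
                  self.energy_scale, self.time_scale)
        factor = 1.0
        for s, e in zip(scales, signature):
            if not isinstance(e, int):
                raise ValueError(f"non-integer exponent {e!r} in signature")
            factor *= s ** e
        return factor


def build_unit_map(temperature_kelvin: float,
                   water_mass_density: float,
                   water_molecules_per_bead: float,
                   reduced_density: float) -> UnitMap:
    """Derive the reduced->SI unit map by water-density matching.

    One solvent bead stands for ``water_molecules_per_bead`` water
    molecules and the reduced bead number density is ``reduced_density``
    (beads per r_C^3).  Matching the coarse-grained mass density to the
    experimental water density fixes the length scale:

        r_C = (reduced_density * m_bead / rho_water)^(1/3)

    Parameters use SI (K, kg/m^3).
    """
    for name, value in (("temperature_kelvin", temperature_kelvin),
                        ("water_mass_density", water_mass_density),
                        ("water_molecules_per_bead", water_molecules_per_bead),
                        ("reduced_density", reduced_density)):
        if value <= 0:
            raise ValueError(f"{name} must be strictly positive, got {value}")
    mass_scale = water_molecules_per_bead * WATER_MOLAR_MASS / AVOGADRO
    energy_scale = BOLTZMANN * temperature_kelvin
    length_scale = (reduced_density * mass_scale / water_mass_density) ** (1.0 / 3.0)
    return UnitMap(length_scale=length_scale, mass_scale=mass_scale,
                   energy_scale=energy_scale)


def convert(value: float,
            dimension_signature: tuple[int, int, int, int],
            direction: str,
            unit_map: UnitMap) -> float:
    """Convert between reduced and SI units.

    ``direction`` is ``"to_si"`` (reduced -> SI) or ``"to_reduced"``.
    The signature gives integer exponents over (length, mass, energy,
    time); e.g. a force is ``(-1, 0, 1, 0)`` (energy/length) and a
    friction coefficient (mass/time) is ``(0, 1, 0, -1)``.
    """
    factor = unit_map.scale_for(tuple(dimension_signature))
    if direction == "to_si":
        return value * factor
    if direction == "to_reduced":
        return value / factor
    raise ValueError(f"unknown direction {direction!r}; "
                     "use 'to_si' or 'to_reduced'")


def gamma_from_sigma(sigma: float, kT: float) -> float:
    """Friction coefficient from the noise amplitude.

    The fluctuation-dissipation constraint for the DPD thermostat links
    the two amplitudes as ``sigma^2 = 2 * gamma * kT``.
    """
    if kT <= 0:
        raise ValueError(f"kT must be strictly positive, got {kT}")
    return sigma * sigma / (2.0 * kT)


def sigma_from_gamma(gamma: float, kT: float) -> float:
    """Inverse of :func:`gamma_from_sigma` (non-negative root)."""
    if kT <= 0:
        raise ValueError(f"kT must be strictly positive, got {kT}")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return math.sqrt(2.0 * gamma * kT)


def default_unit_map() -> UnitMap:
    """Room-temperature water mapping: 2 H2O per bead, density 3."""
    return build_unit_map(298.15, 997.0, 2, 3)
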