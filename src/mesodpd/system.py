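"""Particle configurations in a cubic periodic (optionally sheared) box."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Configuration:
    """Snapshot of all bead positions and velocities.

    Positions are reduced coordinates wrapped into ``[0, L)^3``.  Under
    Lees-Edwards shear the images across the y boundary are displaced in
    x by ``shear_offset`` (itself in ``[0, L)``) and move at a relative
    x velocity of ``shear_rate * L``.
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    molecule_id: np.ndarray
    box_edge: float
    shear_offset: float = 0.0
    shear_rate: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.molecule_id = np.ascontiguousarray(self.molecule_id, dtype=np.int64)
        self.species = np.asarray(self.species)
        n = len(self.positions)
        if not (len(self.velocities) == len(self.species)
                == len(self.molecule_id) == n):
            raise ValueError("positions, velocities, species and molecule_id "
                             "must all have the same length")
        if self.box_edge <= 0:
            raise ValueError("box_edge must be > 0")
        if not (0 <= self.shear_offset < self.box_edge):
            raise ValueError("shear_offset must lie in [0, L)")
        self.wrap()

    def __len__(self) -> int:
        return len(self.positions)

    def wrap(self) -> None:
        """Fold positions into the primary box (Lees-Edwards aware)."""
        L = self.box_edge
        # y crossings shift x by the accumulated boundary offset
        ny = np.floor(self.positions[:, 1] / L)
        if self.shear_offset != 0.0 or self.shear_rate != 0.0:
            self.positions[:, 0] -= ny * self.shear_offset
            self.velocities[:, 0] -= ny * self.shear_rate * L
        self.positions[:, 1] -= ny * L
        self.positions[:, 0] %= L
        self.positions[:, 2] %= L
        # guard against -0.0 / L edge cases from the modulo
        np.clip(self.positions, 0.0, np.nextafter(L, 0.0), out=self.positions)

    def copy(self) -> "Configuration":
        return Configuration(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            molecule_id=self.molecule_id.copy(),
            box_edge=self.box_edge,
            shear_offset=self.shear_offset,
            shear_rate=self.shear_rate,
            time=self.time,
        )

    def kinetic_temperature(self) -> float:
        """Instantaneous kT from the kinetic energy (unit bead mass)."""
        return float((self.velocities ** 2).sum() / (3 * len(self)))

    def species_indices(self, order) -> np.ndarray:
        """Map species labels to integer indices in the given order."""
        lookup = {name: i for i, name in enumerate(order)}
        return np.array([lookup[s] for s in self.species], dtype=np.int64)


def minimum_image(dr: np.ndarray, L: float,
                  shear_offset: float = 0.0) -> np.ndarray:
    """Minimum-image displacement vectors, Lees-Edwards aware.

    ``dr`` has shape (..., 3).  When the image convention crosses the y
    boundary the x component is corrected by the shear offset.
    """
    dr = np.array(dr, dtype=np.float64, copy=True)
    ny = np.round(dr[..., 1] / L)
    dr[..., 1] -= ny * L
    dr[..., 0] -= ny * shear_offset
    dr[..., 0] -= L * np.round(dr[..., 0] / L)
    dr[..., 2] -= L * np.round(dr[..., 2] / L)
    return dr
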