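"""Slater-smeared electrostatics under periodic boundaries.

Charged beads carry an exponentially decaying (Slater-type) charge
cloud, which keeps the Coulomb interaction finite when soft DPD beads
overlap.  The pair potential between beads i and j is

    u(r) = Gamma * q_i * q_j / (4 pi r) * [1 - (1 + beta r) e^(-2 beta r)]

which tends to the point-charge Coulomb form at large r and to the
finite value ``Gamma q_i q_j beta / (4 pi)`` at contact.  Periodic sums
are evaluated by Ewald splitting: the point-charge part splits into an
erfc real-space term and a reciprocal sum, and the (short-ranged)
smearing correction is added in real space.  A direct image-sum
reference implementation ships for cross-validation on small boxes.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels
from .forcefield import ElectrostaticsParams
from .system import Configuration


def slater_pair_energy(r: float, qi: float, qj: float,
                       params: ElectrostaticsParams) -> float:
    """Closed-form smeared pair energy at separation ``r`` (no images)."""
    ke = params.coupling / (4.0 * math.pi)
    b = params.slater_beta
    if r == 0:
        return ke * qi * qj * b
    return ke * qi * qj / r * (1.0 - (1.0 + b * r) * math.exp(-2.0 * b * r))


def slater_pair_force(r: float, qi: float, qj: float,
                      params: ElectrostaticsParams) -> float:
    """Magnitude of -du/dr along the separation (positive = repulsive)."""
    ke = params.coupling / (4.0 * math.pi)
    b = params.slater_beta
    if r == 0:
        return 0.0
    ex = math.exp(-2.0 * b * r)
    return ke * qi * qj * (1.0 / r ** 2
                           - ex * (1.0 / r ** 2 + 2.0 * b / r + 2.0 * b * b))


def tune_ewald(L: float, params: ElectrostaticsParams,
               tolerance: float = 1e-4) -> tuple[float, float, float, int]:
    """Choose (real cutoff, smearing range, alpha, reciprocal extent).

    The erfc cutoff targets ``erfc(alpha r) ~ tolerance``; the smearing
    correction range covers the exponential tail down to the same
    tolerance and may exceed half the box (images are summed).
    """
    rcut = params.real_cutoff
    if rcut is None:
        rcut = min(0.499 * L, 3.5)
    x = math.sqrt(max(-math.log(tolerance * math.sqrt(math.pi)), 1.0))
    alpha = params.alpha if params.alpha is not None else x / rcut
    rsm = max(math.log(4.0 / tolerance) / (2.0 * params.slater_beta) + 1.0,
              rcut)
    if params.kmax is not None:
        nmax = params.kmax
    else:
        kcut = 2.0 * alpha * 3.1
        nmax = max(int(math.ceil(kcut * L / (2.0 * math.pi))), 1)
    return rcut, rsm, alpha, nmax


def electrostatic_forces(configuration: Configuration,
                         charges: np.ndarray,
                         electro_params: ElectrostaticsParams,
                         tolerance: float = 1e-4
                         ) -> tuple[np.ndarray, float]:
    """Per-bead electrostatic forces and total energy (tinfoil boundary).

    The system must be charge-neutral.  Only charged beads enter the
    pair sums; the returned force array covers all beads.
    """
    charges = np.asarray(charges, dtype=np.float64)
    if abs(charges.sum()) > 1e-9:
        raise ValueError(
            f"electrostatics requires a charge-neutral system; "
            f"net charge = {charges.sum()}")
    n = len(configuration)
    forces = np.zeros((n, 3))
    idx = np.nonzero(charges)[0].astype(np.int64)
    if len(idx) == 0:
        return forces, 0.0
    L = configuration.box_edge
    rcut, rsm, alpha, nmax = tune_ewald(L, electro_params, tolerance)
    ke = electro_params.coupling / (4.0 * math.pi)
    e_real = _kernels.ewald_real_and_correction(
        configuration.positions, charges, idx, ke,
        electro_params.slater_beta, alpha, rcut, rsm, L,
        configuration.shear_offset, forces)
    e_k = _kernels.ewald_kspace(
        configuration.positions, charges, idx, ke, alpha, L,
        configuration.shear_offset, nmax, forces)
    e_self = -ke * alpha / math.sqrt(math.pi) * float((charges ** 2).sum())
    return forces, e_real + e_k + e_self


def direct_sum_reference(configuration: Configuration,
                         charges: np.ndarray,
                         electro_params: ElectrostaticsParams,
                         n_shells: int = 12) -> tuple[np.ndarray, float]:
    """Brute-force image sum of the full smeared potential.

    Sums the closed-form pair interaction over all periodic images in a
    cube of ``(2 n_shells + 1)^3`` cells.  Convergence to the tinfoil
    Ewald value requires a zero-dipole charge arrangement; intended only
    for tiny validation systems.
    """
    charges = np.asarray(charges, dtype=np.float64)
    pos = configuration.positions
    L = configuration.box_edge
    idx = np.nonzero(charges)[0]
    ke = electro_params.coupling / (4.0 * math.pi)
    b = electro_params.slater_beta
    n = len(configuration)
    forces = np.zeros((n, 3))
    energy = 0.0
    shifts = np.arange(-n_shells, n_shells + 1) * L
    images = np.stack(np.meshgrid(shifts, shifts, shifts, indexing="ij"),
                      axis=-1).reshape(-1, 3)
    for a_i, i in enumerate(idx):
        for j in idx[a_i:]:
            qq = ke * charges[i] * charges[j]
            d = pos[i] - pos[j] + images
            r = np.linalg.norm(d, axis=1)
            keep = r > 1e-12  # drop the zero-shift self image
            d, r = d[keep], r[keep]
            ex = np.exp(-2.0 * b * r)
            pair_e = qq / r * (1.0 - (1.0 + b * r) * ex)
            if i == j:
                energy += 0.5 * pair_e.sum()  # self images counted once
            else:
                energy += pair_e.sum()
                fmag = qq * (1.0 / r ** 2
                             - ex * (1.0 / r ** 2 + 2.0 * b / r + 2.0 * b * b))
                fv = ((fmag / r)[:, None] * d).sum(axis=0)
                forces[i] += fv
                forces[j] -= fv
    return forces, energy
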