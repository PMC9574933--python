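"""Idealised particle configurations with known ground truth.

These generators build geometric scaffolds of the structures the
analyses assume — fields of spherical micelles, tilted lamellar stacks
and hexagonal rod lattices — so that every analysis stage can be
validated by round-trip against the generating parameters without
running long simulations.  Whole molecules are placed (straight
l0-spaced chains), water and counterions fill the box to the standard
reduced density of 3, and positional thermal disorder is emulated by
seeded isotropic gaussian jitter.  The fixtures are *not*
thermodynamically realistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .forcefield import ForceField, default_force_field
from .mesophase import gauss_reduce
from .system import Configuration
from .topology import build_slens


@dataclass
class FixtureSpec:
    """Declarative fixture description (see the make_* functions)."""

    kind: str
    box_edge: float
    noise_sigma: float = 0.0
    seed: int = 0
    params: dict = field(default_factory=dict)

    def build(self, force_field: ForceField | None = None):
        maker = {"micellar": make_micelle_field,
                 "lamellar": make_lamellar,
                 "hexagonal": make_hexagonal}[self.kind]
        return maker(box_edge=self.box_edge, noise_sigma=self.noise_sigma,
                     seed=self.seed, force_field=force_field, **self.params)


def _chain_positions(anchor, direction, topology, force_field):
    """Straight chain from the innermost tail bead outward."""
    l0s = [b[2] for b in topology.bonds]
    pos = [np.asarray(anchor, dtype=float)]
    for l0 in l0s:
        pos.append(pos[-1] + l0 * direction)
    return np.array(pos)


def _assemble(chains, chain_species, na_positions, water_positions, L,
              noise_sigma, rng):
    species: list[str] = []
    mols: list[int] = []
    blocks: list[np.ndarray] = []
    mid = 0
    for p, spc in zip(chains, chain_species):
        blocks.append(p)
        species.extend(spc)
        mols.extend([mid] * len(spc))
        mid += 1
    if len(na_positions):
        blocks.append(np.asarray(na_positions))
        species.extend(["Na"] * len(na_positions))
        mols.extend(range(mid, mid + len(na_positions)))
        mid += len(na_positions)
    if len(water_positions):
        blocks.append(np.asarray(water_positions))
        species.extend(["W"] * len(water_positions))
        mols.extend(range(mid, mid + len(water_positions)))
        mid += len(water_positions)
    pos = np.vstack(blocks)
    if noise_sigma > 0:
        pos = pos + rng.normal(0.0, noise_sigma, pos.shape)
    return Configuration(positions=pos, velocities=np.zeros_like(pos),
                         species=np.array(species, dtype="<U2"),
                         molecule_id=np.array(mols, dtype=np.int64),
                         box_edge=L)


def _fill_water(rng, L, count, reject=None, max_factor: int = 60):
    """Uniform water positions, rejecting points where ``reject`` is true."""
    out = []
    tries = 0
    while len(out) < count:
        tries += 1
        if tries > max_factor:
            raise ValueError("could not place water: box too crowded")
        cand = rng.uniform(0, L, (max(count * 2, 128), 3))
        if reject is not None:
            cand = cand[~reject(cand)]
        out.extend(cand[:count - len(out)])
    return np.array(out[:count])


# --------------------------------------------------------------------------

def make_micelle_field(sizes, box_edge: float, target_rg=None,
                       ethoxylation: int = 0, noise_sigma: float = 0.0,
                       seed: int = 0, fill_water: bool = True,
                       reduced_density: float = 3.0,
                       force_field: ForceField | None = None,
                       max_tries: int = 2000):
    """Field of spherical micelles with prescribed aggregation numbers.

    Each micelle packs its molecules' tails in a sphere (radius
    ``sqrt(5/3) * target_rg`` when given, else scaled as N^(1/3)),
    heads on the shell and counterions nearby; micelles are placed so
    that inter-micelle tail gaps exceed the clustering cutoff.
    Returns ``(configuration, ground_truth)`` where the ground truth
    records sizes, centres and the realised per-micelle R_G.
    """
    ff = force_field if force_field is not None else default_force_field()
    rng = np.random.default_rng(seed)
    L = box_edge
    sizes = list(sizes)
    top = build_slens(ethoxylation, ff)
    chain_len = sum(b[2] for b in top.bonds)
    tail_span = sum(b[2] for b in top.bonds[:3])
    if target_rg is None:
        # core radius from packing the tails at the standard density
        radii = [(3.0 * n * 4 / (4.0 * math.pi * reduced_density)) ** (1 / 3)
                 for n in sizes]
    else:
        tg = list(np.broadcast_to(np.asarray(target_rg, float), len(sizes)))
        radii = [math.sqrt(5.0 / 3.0) * t for t in tg]

    # place centres with safe gaps (rejection sampling)
    centers = []
    for k, rad in enumerate(radii):
        placed = False
        for _ in range(max_tries):
            c = rng.uniform(0, L, 3)
            ok = True
            for c2, r2 in zip(centers, radii):
                d = c - c2
                d -= L * np.round(d / L)
                if np.linalg.norm(d) < rad + r2 + chain_len + 2.5:
                    ok = False
                    break
            if ok:
                centers.append(c)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"cannot pack micelle {k} (radius {rad:.2f}) into L={L}")

    chains, chain_species, nas = [], [], []
    truth_members = []
    for c, n_agg, rad in zip(centers, sizes, radii):
        members = []
        inner_max = max(rad - tail_span, 0.25 * rad)
        for _ in range(n_agg):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r0 = inner_max * rng.uniform() ** (1 / 3)
            p = _chain_positions(c + r0 * u, u, top, ff)
            chains.append(p)
            chain_species.append(top.bead_sequence)
            nas.append(c + (rad + 0.8) * u)
            members.append(p)
        truth_members.append(np.vstack(members))

    realised_rg = []
    for m in truth_members:
        com = m.mean(axis=0)
        realised_rg.append(float(np.sqrt(((m - com) ** 2).sum(axis=1)
                                         .mean())))

    total = int(round(reduced_density * L ** 3))
    n_water = total - sum(len(p) for p in chains) - len(nas)
    if n_water < 0:
        raise ValueError("micelle field exceeds the bead budget")
    water = np.empty((0, 3))
    if fill_water and n_water > 0:
        cen = np.array(centers)
        rad_arr = np.array(radii)

        def inside(pts):
            d = pts[:, None, :] - cen[None, :, :]
            d -= L * np.round(d / L)
            return (np.linalg.norm(d, axis=2)
                    < rad_arr[None, :] + 1.0).any(axis=1)

        water = _fill_water(rng, L, n_water, reject=inside)

    cfg = _assemble(chains, chain_species, nas, water, L, noise_sigma, rng)
    truth = {"sizes": sizes, "centers": np.array(centers),
             "target_rg": None if target_rg is None else target_rg,
             "realised_rg": realised_rg, "seed": seed}
    return cfg, truth


# --------------------------------------------------------------------------

def make_lamellar(box_edge: float, kappa, tilt_axis: int = 2,
                  ethoxylation: int = 0,
                  surfactant_fraction: float = 0.45,
                  noise_sigma: float = 0.0, seed: int = 0,
                  n_frames: int = 1, bridge_rate: float = 0.0,
                  bridge_radius: float = 2.5,
                  allow_incommensurate: bool = False,
                  reduced_density: float = 3.0,
                  force_field: ForceField | None = None):
    """Tilted lamellar stack of alternating surfactant/water slabs.

    ``kappa`` is an integer (stack normal along the ``tilt_axis``) or
    an integer triple of layer projections; the spacing is then
    ``d = L / sqrt(sum kappa_i^2)``, commensurate with the periodic
    box.  A float triple is rejected unless ``allow_incommensurate``.
    With ``bridge_rate > 0`` each generated frame independently
    carries a water bridge through one surfactant slab with that
    probability.  Returns ``(frames, ground_truth)``; ``frames`` is a
    single configuration when ``n_frames == 1``.
    """
    ff = force_field if force_field is not None else default_force_field()
    rng = np.random.default_rng(seed)
    L = box_edge
    if np.isscalar(kappa):
        kvec = np.zeros(3)
        kvec[tilt_axis] = float(kappa)
    else:
        kvec = np.asarray(kappa, dtype=float)
    if not allow_incommensurate and np.any(np.abs(kvec - np.round(kvec))
                                           > 1e-9):
        raise ValueError(
            f"kappa projections {kvec} are not integers; the stack would be "
            "incommensurate with the box (pass allow_incommensurate=True)")
    knorm = float(np.linalg.norm(kvec))
    director = kvec / knorm
    d = L / knorm
    axis = int(np.argmax(np.abs(director)))
    kappa_count = int(round(abs(kvec[axis])))
    theta = math.degrees(math.acos(min(abs(director[axis]), 1.0)))

    top = build_slens(ethoxylation, ff)
    beads_per_chain = top.n_beads
    total = int(round(reduced_density * L ** 3))
    n_chains = int(surfactant_fraction * total / (beads_per_chain + 1))
    slab_half = surfactant_fraction * d / 2.0
    chain_span = sum(b[2] for b in top.bonds)

    def phase(pts):
        return np.mod(pts @ director, d)

    def make_frame(frame_seed, with_bridge):
        frng = np.random.default_rng(frame_seed)
        bridge_center = frng.uniform(0, L, 3) if with_bridge else None

        def in_bridge(pts):
            if bridge_center is None:
                return np.zeros(len(pts), dtype=bool)
            dvec = pts - bridge_center
            dvec -= L * np.round(dvec / L)
            # cylinder along the director through one slab
            perp = dvec - np.outer(dvec @ director, director)
            axial = np.abs(dvec @ director)
            return (np.linalg.norm(perp, axis=1) < bridge_radius) \
                & (axial < d / 2)

        chains, chain_species, nas = [], [], []
        placed = 0
        guard = 0
        while placed < n_chains:
            guard += 1
            if guard > 200 * n_chains:
                raise ValueError("lamellar placement stalled")
            p = frng.uniform(0, L, 3)
            s = phase(p[None, :])[0]
            # snap to the nearest surfactant slab mid-plane
            mid = d / 2.0
            leaf = 1.0 if s >= mid else -1.0
            base = p + (mid - s) * director  # point on the slab mid-plane
            head_pos = base + leaf * slab_half * director
            if bridge_center is not None and in_bridge(base[None, :])[0]:
                continue
            # chain from head inward
            cp = _chain_positions(head_pos, -leaf * director, top, ff)[::-1]
            # sequence order: tails first, head last (build_slens order)
            chains.append(cp)
            chain_species.append(top.bead_sequence)
            na = base + leaf * (slab_half + 0.6) * director
            nas.append(na)
            placed += 1

        n_water = total - placed * (beads_per_chain + 1)

        def reject(pts):
            s = phase(pts)
            in_slab = np.abs(s - d / 2.0) < slab_half + 0.2
            return in_slab & ~in_bridge(pts)

        water = _fill_water(rng=frng, L=L, count=n_water, reject=reject)
        return _assemble(chains, chain_species, nas, water, L,
                         noise_sigma, frng)

    sub = rng.integers(0, 2 ** 31 - 1, size=n_frames)
    bridged = [bool(rng.uniform() < bridge_rate) for _ in range(n_frames)]
    frames = [make_frame(int(sub[k]), bridged[k]) for k in range(n_frames)]
    truth = {"d": d, "kappa": kappa_count, "kappa_vector": kvec,
             "theta": theta, "director": director, "axis": axis,
             "bridged_frames": bridged, "seed": seed}
    return (frames[0] if n_frames == 1 else frames), truth


# --------------------------------------------------------------------------

def make_hexagonal(box_edge: float, a, b, rod_axis: int = 0,
                   ethoxylation: int = 0, rod_radius: float = 2.0,
                   noise_sigma: float = 0.0, seed: int = 0,
                   allow_incommensurate: bool = False,
                   reduced_density: float = 3.0,
                   force_field: ForceField | None = None):
    """Hexagonal lattice of surfactant rods along a box axis.

    ``a`` and ``b`` are 2D lattice vectors in the transverse plane;
    they must tile the L x L periodic cell (integer combinations
    generate both (L,0) and (0,L)) unless flagged.  Tails fill rod
    cylinders, heads sit on the rod surface, water and ions fill the
    remainder to the standard density.
    """
    ff = force_field if force_field is not None else default_force_field()
    rng = np.random.default_rng(seed)
    L = box_edge
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    B = np.column_stack([a, b])
    N = L * np.linalg.inv(B)
    if not allow_incommensurate and np.any(np.abs(N - np.round(N)) > 1e-9):
        raise ValueError(
            "lattice vectors do not tile the periodic cell "
            "(pass allow_incommensurate=True)")
    m = int(round(abs(np.linalg.det(np.round(N)))))

    # lattice points in the primary transverse cell
    pts = set()
    K = m + 2
    for i in range(-K, K + 1):
        for j in range(-K, K + 1):
            p = np.mod(i * a + j * b, L)
            pts.add((round(p[0], 6) % L, round(p[1], 6) % L))
    centers = np.array(sorted(pts))
    if len(centers) != m:
        centers = centers[:m]
    ra, rb = gauss_reduce(a, b)
    nn = sorted([np.linalg.norm(ra), np.linalg.norm(rb),
                 np.linalg.norm(ra - rb)])
    if 2 * rod_radius + 1.0 > nn[0]:
        raise ValueError(
            f"rod radius {rod_radius} overlaps neighbouring rods "
            f"(nearest-neighbour distance {nn[0]:.2f})")

    top = build_slens(ethoxylation, ff)
    beads_per_chain = top.n_beads
    chain_span = sum(bd[2] for bd in top.bonds)
    total = int(round(reduced_density * L ** 3))
    volume_fraction = len(centers) * math.pi * rod_radius ** 2 / (L * L)
    n_chains = int(volume_fraction * total / (beads_per_chain + 1))

    tr = [ax for ax in range(3) if ax != rod_axis]
    chains, chain_species, nas = [], [], []
    inner_max = max(rod_radius - chain_span - 0.1, 0.2)
    for k in range(n_chains):
        c2 = centers[k % len(centers)]
        x = rng.uniform(0, L)
        phi = rng.uniform(0, 2 * math.pi)
        u2 = np.array([math.cos(phi), math.sin(phi)])
        rho0 = inner_max * math.sqrt(rng.uniform())
        anchor = np.zeros(3)
        anchor[rod_axis] = x
        anchor[tr[0]] = c2[0] + rho0 * u2[0]
        anchor[tr[1]] = c2[1] + rho0 * u2[1]
        u3 = np.zeros(3)
        u3[tr[0]], u3[tr[1]] = u2
        p = _chain_positions(anchor, u3, top, ff)
        chains.append(p)
        chain_species.append(top.bead_sequence)
        na = anchor + (rod_radius - rho0 + 0.8) * u3
        nas.append(na)

    n_water = total - n_chains * (beads_per_chain + 1)

    def reject(pts3):
        d2 = pts3[:, tr][:, None, :] - centers[None, :, :]
        d2 -= L * np.round(d2 / L)
        return (np.linalg.norm(d2, axis=2) < rod_radius + 0.5).any(axis=1)

    water = _fill_water(rng, L, n_water, reject=reject)
    cfg = _assemble(chains, chain_species, nas, water, L, noise_sigma, rng)
    r_s = float(sum(nn) / 3.0)
    truth = {"a": a, "b": b, "reduced_a": ra, "reduced_b": rb,
             "centers": centers, "r_s": r_s, "rod_axis": rod_axis,
             "n_rods": len(centers), "seed": seed}
    return cfg, truth


def validate_fixture_composition(configuration: Configuration,
                                 force_field: ForceField | None = None,
                                 reduced_density: float = 3.0) -> None:
    """Assert the fixture meets the bead budget and charge neutrality."""
    ff = force_field if force_field is not None else default_force_field()
    L = configuration.box_edge
    expected = int(round(reduced_density * L ** 3))
    if len(configuration) != expected:
        raise ValueError(f"bead count {len(configuration)} != {expected}")
    q = sum(ff.charge_of(str(s)) for s in configuration.species)
    if q != 0:
        raise ValueError(f"fixture carries net charge {q}")
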