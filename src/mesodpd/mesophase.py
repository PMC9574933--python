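"""Lamellar and hexagonal mesophase periodicity analysis.

Periodic boundaries quantise the periodicities a mesophase can adopt.
A lamellar stack with director at polar angle theta to its matched box
axis must satisfy ``L cos(theta) = kappa d`` with kappa an integer
layer count; generalised to integer layer projections in every box
dimension this restricts the d-spacing to ``d = L / sqrt(k_x^2 + k_y^2
+ k_z^2)``.  A hexagonal rod lattice with rods along a box axis must
tile the transverse L x L cell: integer combinations of its lattice
vectors a, b must generate both periodic images (L, 0) and (0, L),
i.e. the rod lattice is a superlattice of (L Z)^2.  Near-hexagonal
cells are selected by requiring the three nearest-neighbour distances
|a|, |b|, |a - b| to differ pairwise by at most a cutoff d_co, and the
average inter-rod spacing is r_S = (|a| + |b| + |a - b|) / 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .system import Configuration


class PhaseAnalysisError(ValueError):
    """Raised when a configuration does not exhibit the assumed phase."""


def round_sf(x: float, sf: int = 3) -> float:
    """Round to ``sf`` significant figures (catalog deduplication)."""
    if x == 0:
        return 0.0
    return round(x, sf - 1 - int(math.floor(math.log10(abs(x)))))


# --------------------------------------------------------------------------
# lamellar
# --------------------------------------------------------------------------

def _end_to_end_vectors(configuration: Configuration,
                        molecule_ids=None) -> np.ndarray:
    """Unit head-to-tail vectors of multi-bead molecules (chain unwrap)."""
    mol = configuration.molecule_id
    pos = configuration.positions
    L = configuration.box_edge
    if molecule_ids is None:
        ids, counts = np.unique(mol, return_counts=True)
        molecule_ids = ids[counts >= 2]
    vecs = []
    order = np.argsort(mol, kind="stable")
    sorted_mol = mol[order]
    starts = np.searchsorted(sorted_mol, molecule_ids, side="left")
    ends = np.searchsorted(sorted_mol, molecule_ids, side="right")
    for s, e in zip(starts, ends):
        beads = order[s:e]
        p = pos[beads]
        # chain-unwrap consecutive beads
        d = np.diff(p, axis=0)
        d -= L * np.round(d / L)
        v = d.sum(axis=0)
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            vecs.append(v / norm)
    return np.array(vecs)


def lamellar_director(configuration: Configuration,
                      molecule_ids=None,
                      degeneracy_tol: float = 0.01) -> np.ndarray | None:
    """Principal axis of the nematic (second-moment) tensor.

    Built from molecular end-to-end unit vectors, so it is insensitive
    to the head/tail sign.  Returns ``None`` when the top eigenvalues
    are degenerate within ``degeneracy_tol`` (isotropic system).
    """
    vecs = _end_to_end_vectors(configuration, molecule_ids)
    if len(vecs) < 10:
        raise PhaseAnalysisError("need at least 10 molecules for a director")
    M = vecs.T @ vecs / len(vecs)
    w, v = np.linalg.eigh(M)
    if (w[2] - w[1]) < degeneracy_tol * max(w[2], 1e-30):
        return None
    d = v[:, 2]
    # sign canonicalisation: largest-magnitude component positive
    k = int(np.argmax(np.abs(d)))
    if d[k] < 0:
        d = -d
    return d


def director_polar_angle(director: np.ndarray) -> tuple[int, float]:
    """(matched box axis, polar angle in degrees) of a director."""
    axis = int(np.argmax(np.abs(director)))
    c = abs(float(director[axis])) / float(np.linalg.norm(director))
    return axis, math.degrees(math.acos(min(c, 1.0)))


def layer_count(configuration: Configuration, director: np.ndarray,
                surfactant_species=("C", "E", "S"),
                max_layers: int = 40,
                peak_factor: float = 2.0) -> int:
    """Number of bilayers along the director (discrete Fourier peak).

    The surfactant density projected on the director is periodic with
    wavelength ``L cos(theta) / kappa``; the dominant harmonic of the
    projected box period gives kappa.
    """
    species = np.asarray(configuration.species)
    sel = np.isin(species, list(surfactant_species))
    if not np.any(sel):
        raise PhaseAnalysisError("no surfactant beads present")
    d = np.asarray(director, float)
    d = d / np.linalg.norm(d)
    axis, theta = director_polar_angle(d)
    period = configuration.box_edge * math.cos(math.radians(theta))
    s = configuration.positions[sel] @ d
    kappas = np.arange(1, max_layers + 1)
    phases = np.exp(2j * np.pi * np.outer(kappas, s) / period)
    power = np.abs(phases.mean(axis=1)) ** 2
    k = int(np.argmax(power))
    background = np.median(np.delete(power, k))
    # an unstructured system has power ~ Exp(mean 1/n) at every harmonic
    noise_floor = 25.0 / sel.sum()
    if power[k] < max(peak_factor * background, noise_floor):
        raise PhaseAnalysisError(
            "no dominant density harmonic: configuration is not lamellar")
    return int(kappas[k])


def d_spacing(L: float, theta: float, kappa: int) -> float:
    """Lamellar repeat distance ``d = L cos(theta) / kappa`` (theta deg)."""
    if kappa < 1:
        raise ValueError("kappa must be a positive integer")
    if not (0 <= theta < 90):
        raise ValueError("theta must lie in [0, 90) degrees")
    return L * math.cos(math.radians(theta)) / kappa


@dataclass
class LamellarMetrics:
    director: np.ndarray
    axis: int
    theta: float
    kappa: int
    d: float
    perfect: bool | None = None
    bridge_fraction: float | None = None


def analyze_lamellar(configuration: Configuration,
                     molecule_ids=None) -> LamellarMetrics:
    """Full lamellar pipeline: director -> angle -> layer count -> d."""
    director = lamellar_director(configuration, molecule_ids)
    if director is None:
        raise PhaseAnalysisError("no nematic director (isotropic)")
    axis, theta = director_polar_angle(director)
    kappa = layer_count(configuration, director)
    return LamellarMetrics(director=director, axis=axis, theta=theta,
                           kappa=kappa,
                           d=d_spacing(configuration.box_edge, theta, kappa))


@dataclass
class SpacingCatalog:
    """Sorted, deduplicated list of PBC-allowed spacings."""

    box_edge: float
    values: np.ndarray                      # spacings, 3 s.f., descending
    indices: list[tuple]                    # integer indices per entry
    details: list[dict] = field(default_factory=list)
    d_co: float | None = None

    def __contains__(self, value: float) -> bool:
        return round_sf(float(value)) in set(self.values.tolist())

    def __len__(self) -> int:
        return len(self.values)


def allowed_d_spacings(L: float, d_min: float, d_max: float
                       ) -> SpacingCatalog:
    """All lamellar spacings ``L/sqrt(kx^2+ky^2+kz^2)`` within range."""
    if not (0 < d_min < d_max):
        raise ValueError("require 0 < d_min < d_max")
    kmax = int(math.ceil(L / d_min))
    seen: dict[float, tuple] = {}
    for kx in range(0, kmax + 1):
        for ky in range(0, kmax + 1):
            for kz in range(0, kmax + 1):
                s2 = kx * kx + ky * ky + kz * kz
                if s2 == 0:
                    continue
                d = L / math.sqrt(s2)
                if not (d_min <= d <= d_max):
                    continue
                key = round_sf(d)
                if key not in seen:
                    seen[key] = (kx, ky, kz)
    values = np.array(sorted(seen, reverse=True))
    return SpacingCatalog(box_edge=L, values=values,
                          indices=[seen[v] for v in values])


# --------------------------------------------------------------------------
# hexagonal
# --------------------------------------------------------------------------

def gauss_reduce(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Lagrange-Gauss reduction of a 2D lattice basis.

    Returns the two shortest independent lattice vectors, signed so
    that ``|a - b| <= |a + b|`` (the three nearest-neighbour lengths
    are then |a|, |b| and |a - b|).
    """
    a = np.array(a, dtype=float)
    b = np.array(b, dtype=float)
    if a @ a > b @ b:
        a, b = b, a
    while True:
        m = round(float(a @ b) / float(a @ a))
        b = b - m * a
        if b @ b >= a @ a:
            break
        a, b = b, a
    if (a - b) @ (a - b) > (a + b) @ (a + b):
        b = -b
    return a, b


def _cell_lengths(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    return (float(np.linalg.norm(a)), float(np.linalg.norm(b)),
            float(np.linalg.norm(a - b)))


def enumerate_superlattices(L: float, max_index: int):
    """All 2D lattices containing (L Z)^2, by Hermite normal form.

    Yields ``(index, (a, b))`` with a Gauss-reduced basis; each lattice
    appears exactly once.  ``index`` equals the number of rods the
    lattice places in the L x L transverse cell.
    """
    for a1 in range(1, max_index + 1):
        for a2 in range(1, max_index // a1 + 1):
            m = a1 * a2
            for c in range(0, a2):
                a = np.array([L * a2 / m, 0.0])
                b = np.array([-L * c / m, L * a1 / m])
                yield m, gauss_reduce(a, b)


def allowed_r_s(L: float, d_co: float = 1.5,
                r_min: float = 7.5, r_max: float = 11.0,
                mirror_distinct: bool = False) -> SpacingCatalog:
    """PBC-allowed average inter-rod spacings in (r_min, r_max).

    Enumerates every rod lattice commensurate with the transverse cell,
    keeps near-hexagonal cells (pairwise nearest-neighbour length
    differences <= d_co) and deduplicates the three-distance average
    r_S at 3 significant figures.  Mirror-image cells share all three
    lengths, so ``mirror_distinct`` only affects the recorded cell
    count, never the value list.
    """
    if d_co <= 0:
        raise ValueError("d_co must be > 0")
    # smallest near-hexagonal cell area at r_min bounds the lattice index
    max_index = int(math.ceil(L * L / (math.sqrt(3.0) / 2.0 * r_min ** 2)
                              * 1.6)) if r_min > 0 else 4 * int(L)
    seen: dict[float, dict] = {}
    n_cells = 0
    for m, (a, b) in enumerate_superlattices(L, max_index):
        l1, l2, l3 = _cell_lengths(a, b)
        lengths = sorted((l1, l2, l3))
        if lengths[2] - lengths[0] > d_co:
            continue
        rs = (l1 + l2 + l3) / 3.0
        if not (r_min < rs < r_max):
            continue
        n_cells += 1
        key = round_sf(rs)
        if key not in seen:
            seen[key] = {"a": a, "b": b, "index": m,
                         "lengths": (l1, l2, l3), "r_s": rs}
    values = np.array(sorted(seen))
    details = [seen[v] for v in values]
    cat = SpacingCatalog(box_edge=L, values=values,
                         indices=[d["index"] for d in details],
                         details=details, d_co=d_co)
    if mirror_distinct:
        for d in cat.details:
            d["n_cells_counted"] = n_cells
    return cat


def detect_rods(configuration: Configuration,
                tail_species=frozenset({"C"}),
                cluster_cutoff: float = 1.2,
                min_rods: int = 3) -> tuple[np.ndarray, int]:
    """Rod centres in the transverse plane and the rod axis.

    The rod axis is the box axis along which the tail density is most
    nearly translation-invariant; tails projected on the transverse
    plane are clustered into rods (periodic), and elongated or
    percolating transverse clusters reject the configuration as
    non-hexagonal.
    """
    species = np.asarray(configuration.species)
    sel = np.isin(species, sorted(tail_species))
    if not np.any(sel):
        raise PhaseAnalysisError("no tail beads present")
    pos = configuration.positions[sel]
    L = configuration.box_edge

    # rod axis: the projection onto the transverse plane of the true
    # axis is maximally structured (sharp spots -> high 2D contrast)
    contrasts = []
    nbins = max(int(L), 8)
    for ax in range(3):
        t = [a for a in range(3) if a != ax]
        h, _, _ = np.histogram2d(pos[:, t[0]], pos[:, t[1]],
                                 bins=nbins, range=((0, L), (0, L)))
        contrasts.append(h.std() / max(h.mean(), 1e-12))
    axis = int(np.argmax(contrasts))
    tr = [a for a in range(3) if a != axis]
    pts = np.mod(pos[:, tr], L)
    pts[pts >= L] = 0.0

    tree = cKDTree(pts, boxsize=L)
    pairs = tree.query_pairs(cluster_cutoff, output_type="ndarray")
    n = len(pts)
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_clusters, labels = connected_components(graph, directed=False)

    centers = []
    for c in range(n_clusters):
        p = pts[labels == c]
        if len(p) < 3:
            continue
        # circular mean per transverse dimension
        ang = 2 * np.pi * p / L
        mean_ang = np.arctan2(np.sin(ang).mean(axis=0),
                              np.cos(ang).mean(axis=0))
        center = np.mod(mean_ang / (2 * np.pi) * L, L)
        # compactness: reject stripes/percolating transverse clusters
        d = p - center
        d -= L * np.round(d / L)
        if np.max(np.abs(d)) > L / 4:
            raise PhaseAnalysisError(
                "transverse tail clusters are extended: not a rod lattice")
        centers.append(center)
    if len(centers) < min_rods:
        raise PhaseAnalysisError(
            f"found {len(centers)} rods; need >= {min_rods}")
    return np.array(centers), axis


@dataclass
class HexagonalMetrics:
    rod_axis: int
    a: np.ndarray
    b: np.ndarray
    lengths: tuple[float, float, float]
    r_s: float
    orientation: str
    commensurate: bool
    residual: float


def fit_hexagonal_lattice(rod_centers: np.ndarray, L: float,
                          d_co: float = 1.5, rod_axis: int = 0,
                          residual_tol: float = 0.5,
                          angle_tol: float = 5.0) -> HexagonalMetrics:
    """Fit a PBC-commensurate lattice to rod centres.

    The rod count fixes the lattice index; every commensurate lattice
    of that index is scored by how tightly the centres collapse onto a
    single lattice offset, and the best fit supplies the reduced basis
    and the three-distance average r_S.  A best residual above
    ``residual_tol`` marks the arrangement incommensurate.  Orientation
    is "parallel" when a nearest-neighbour vector aligns with the
    first transverse axis (the shear plane) and "perpendicular" when
    one aligns with the second.
    """
    centers = np.asarray(rod_centers, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 2 or len(centers) < 3:
        raise ValueError("need at least 3 rod centres in the plane")
    m = len(centers)
    best = None
    for idx, (a, b) in enumerate_superlattices(L, m):
        if idx != m:
            continue
        B = np.column_stack([a, b])
        frac = np.linalg.solve(B, centers.T).T % 1.0
        # common lattice offset via circular mean of fractional coords
        ang = 2 * np.pi * frac
        offset = np.arctan2(np.sin(ang).mean(axis=0),
                            np.cos(ang).mean(axis=0)) / (2 * np.pi)
        dev = (frac - offset + 0.5) % 1.0 - 0.5
        err = dev @ B.T
        resid = float(np.sqrt((err ** 2).sum(axis=1).mean()))
        if best is None or resid < best[0]:
            best = (resid, a, b)
    if best is None:
        raise PhaseAnalysisError(
            f"no commensurate lattice with {m} rods exists for L={L}")
    resid, a, b = best
    l1, l2, l3 = _cell_lengths(a, b)
    rs = (l1 + l2 + l3) / 3.0

    orientation = "other"
    nn = [a, b, a - b]
    for v in nn:
        ang = math.degrees(math.atan2(abs(v[1]), abs(v[0])))
        if ang < angle_tol:
            orientation = "parallel"
            break
        if ang > 90 - angle_tol:
            orientation = "perpendicular"
            break
    return HexagonalMetrics(rod_axis=rod_axis, a=a, b=b,
                            lengths=(l1, l2, l3), r_s=rs,
                            orientation=orientation,
                            commensurate=resid <= residual_tol,
                            residual=resid)


def analyze_hexagonal(configuration: Configuration,
                      tail_species=frozenset({"C"}),
                      d_co: float = 1.5) -> HexagonalMetrics:
    """Full hexagonal pipeline: rod detection -> lattice fit -> r_S."""
    centers, axis = detect_rods(configuration, tail_species)
    return fit_hexagonal_lattice(centers, configuration.box_edge,
                                 d_co=d_co, rod_axis=axis)


# --------------------------------------------------------------------------
# phase classification and the concentration model
# --------------------------------------------------------------------------

def _percolation_dimensions(configuration: Configuration, mask,
                            cutoff: float = 1.0) -> int:
    """Number of box dimensions the largest selected-bead cluster spans."""
    pos = configuration.positions[mask]
    L = configuration.box_edge
    if len(pos) == 0:
        return 0
    wrapped = np.mod(pos, L)
    wrapped[wrapped >= L] = 0.0
    tree = cKDTree(wrapped, boxsize=L)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    n = len(pos)
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    ncl, labels = connected_components(graph, directed=False)
    largest = int(np.argmax(np.bincount(labels)))
    sel = labels == largest
    idx_map = np.nonzero(sel)[0]
    local = {b: k for k, b in enumerate(idx_map)}
    adj: list[list[int]] = [[] for _ in idx_map]
    for p, q in pairs:
        if sel[p] and sel[q]:
            adj[local[p]].append(local[q])
            adj[local[q]].append(local[p])
    # BFS with image bookkeeping; a wrap mismatch marks percolation per dim
    p = pos[sel]
    nloc = len(p)
    visited = np.zeros(nloc, dtype=bool)
    shift = np.zeros((nloc, 3))
    percolates = np.zeros(3, dtype=bool)
    visited[0] = True
    queue = [0]
    while queue:
        i = queue.pop()
        pi = p[i] + shift[i]
        for j in adj[i]:
            dj = p[j] - pi
            expected = -L * np.round(dj / L)
            if not visited[j]:
                shift[j] = expected
                visited[j] = True
                queue.append(j)
            else:
                mism = np.abs(shift[j] - expected) > L / 2
                percolates |= mism
    return int(percolates.sum())


def expected_water_slabs(L: float, director: np.ndarray, d: float) -> int:
    """Distinct periodic water slabs of a commensurate lamellar stack.

    The box cuts the stack into layer slices, but periodic translations
    identify slices whose indices differ by any integer layer
    projection; the number of distinct slabs is therefore the gcd of
    the nonzero projections (kappa for an axis-aligned stack).
    """
    proj = np.abs(np.asarray(director, float)) * L / d
    ints = [int(round(p)) for p in proj if p > 0.25]
    if not ints or any(abs(p - round(p)) > 0.05
                       for p in proj if p > 0.25):
        return 1
    g = ints[0]
    for k in ints[1:]:
        g = math.gcd(g, k)
    return max(g, 1)


def water_layer_bridges(frames, kappa: int, water_species: str = "W",
                        cutoff: float = 1.0,
                        min_layer_fraction: float = 0.2) -> float:
    """Fraction of frames in which water slabs are bridged.

    A perfect lamellar stack of kappa bilayers has kappa disjoint
    macroscopic water slabs; a frame with fewer such water clusters
    has at least one bridge through a surfactant layer.
    """
    frames = list(frames)
    bridged = 0
    for cfg in frames:
        mask = np.asarray(cfg.species) == water_species
        pos = cfg.positions[mask]
        L = cfg.box_edge
        wrapped = np.mod(pos, L)
        wrapped[wrapped >= L] = 0.0
        tree = cKDTree(wrapped, boxsize=L)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        n = len(pos)
        graph = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        ncl, labels = connected_components(graph, directed=False)
        counts = np.bincount(labels)
        macroscopic = int((counts >= min_layer_fraction * n / kappa).sum())
        if macroscopic < kappa:
            bridged += 1
    return bridged / len(frames)


def classify_phase(trajectory, tail_species=frozenset({"C"}),
                   water_species: str = "W", cutoff: float = 1.0,
                   bridge_threshold: float = 0.05) -> str:
    """Label the phase of an (equilibrated) snapshot or trajectory.

    Labels: micellar, worm-like micellar, hexagonal, lamellar-perfect,
    lamellar-imperfect, hexagonal/lamellar, indeterminate.  The rules
    follow the cluster-percolation dimensionality of the tail beads
    (0 -> micellar, 1 -> rods, 2+ -> layers), lattice/layer fits to
    disambiguate, and water-slab bridge counting for lamellar
    (im)perfection.
    """
    frames = [trajectory] if isinstance(trajectory, Configuration) \
        else list(trajectory)
    cfg = frames[-1]
    species = np.asarray(cfg.species)
    mask = np.isin(species, sorted(tail_species))
    dims = _percolation_dimensions(cfg, mask, cutoff)

    hex_ok = False
    hex_metrics = None
    try:
        hex_metrics = analyze_hexagonal(cfg, tail_species)
        hex_ok = hex_metrics.commensurate
    except (PhaseAnalysisError, ValueError):
        pass
    lam_ok = False
    lam_metrics = None
    try:
        lam_metrics = analyze_lamellar(cfg)
        lam_ok = True
    except (PhaseAnalysisError, ValueError):
        pass

    if dims == 0:
        return "micellar"
    if dims == 1:
        return "hexagonal" if hex_ok else "worm-like micellar"
    if dims >= 2:
        if hex_ok and lam_ok:
            return "hexagonal/lamellar"
        if hex_ok:
            return "hexagonal"
        if lam_ok:
            n_slabs = expected_water_slabs(cfg.box_edge,
                                           lam_metrics.director,
                                           lam_metrics.d)
            frac = water_layer_bridges(frames, n_slabs,
                                       water_species, cutoff)
            return ("lamellar-imperfect" if frac > bridge_threshold
                    else "lamellar-perfect")
    return "indeterminate"


def fit_d_model(d_by_concentration: dict, layer_counts: dict,
                volumes: dict) -> tuple[float, dict]:
    """Fit the one-parameter volume model for the lamellar d-spacing.

    The repeat distance is modelled as ``d = d_s * (N_s V_s + N_I V_I +
    N_w V_w) / (N_s V_s)`` with d_s the (concentration-independent)
    surfactant layer thickness.  ``layer_counts`` maps each
    concentration to ``(N_s, N_I, N_w)`` and ``volumes`` supplies
    ``V_s`` (per molecule), ``V_I`` and ``V_w``.  Least-squares over
    >= 3 concentrations; returns (d_s, residuals by concentration).
    """
    concs = sorted(d_by_concentration)
    if len(concs) < 3:
        raise ValueError("need d-spacing observations at >= 3 concentrations")
    x, y = [], []
    for c in concs:
        ns, ni, nw = layer_counts[c]
        vs = ns * volumes["V_s"]
        if vs <= 0:
            raise ValueError(f"non-positive surfactant volume at c={c}")
        x.append((vs + ni * volumes["V_I"] + nw * volumes["V_w"]) / vs)
        y.append(d_by_concentration[c])
    x = np.array(x)
    y = np.array(y)
    d_s = float((x * y).sum() / (x * x).sum())
    residuals = {c: float(y[i] - d_s * x[i]) for i, c in enumerate(concs)}
    return d_s, residuals


def interpolate_ethoxylation(d_0: float, d_1: float, d_poly: float) -> float:
    """Linear interpolation coordinate of a polydisperse spacing.

    ``n_Int = (d_poly - d_0) / (d_1 - d_0)`` places the polydisperse
    d-spacing between the monodisperse n=0 and n=1 results; values
    close to the mixture's mean ethoxylation support predicting
    polydisperse behaviour from monodisperse runs.
    """
    if d_0 == d_1:
        raise ValueError("d_0 and d_1 must differ")
    return (d_poly - d_0) / (d_1 - d_0)
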