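"""Micelle identification and shape statistics.

Micelles are connected clusters of surfactant molecules: two molecules
are in contact when any pair of their hydrophobic tail beads lies
within a cutoff distance (1 reduced unit by default) under periodic
minimum image.  Whole molecules follow their tail assignment.  The
aggregation number N counts molecules per micelle; N_agg is its mean
over micelles.

Micellar shape is summarised by the radius of gyration R_G.  For a
spherical micelle of constant density R_G^3 is proportional to N, so
the profile of R_G^3/N against N is flat where micelles are spherical;
its minimum locates the most-spherical aggregation number, which is
how the optimal micelle size is extracted as a function of
ethoxylation.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .system import Configuration


@dataclass
class MicelleSet:
    """Cluster decomposition of the surfactant molecules in one frame."""

    molecule_ids: np.ndarray          # surfactant molecule ids, sorted
    assignment: np.ndarray            # cluster id per molecule (same order)
    sizes: np.ndarray                 # aggregation number per cluster
    radii: np.ndarray                 # R_G per cluster
    percolating: np.ndarray           # per-cluster percolation flag
    compositions: list[dict[int, int]]  # per-cluster ethoxylation histogram

    @property
    def n_micelles(self) -> int:
        return len(self.sizes)

    def aggregation_number(self, weighting: str = "number") -> float:
        """Mean aggregation number (micelle-count weighted by default)."""
        if len(self.sizes) == 0:
            return 0.0
        if weighting == "number":
            return float(self.sizes.mean())
        if weighting == "mass":
            return float((self.sizes ** 2).sum() / self.sizes.sum())
        raise ValueError(f"unknown weighting {weighting!r}")


def _tail_contact_pairs(positions: np.ndarray, L: float,
                        cutoff: float) -> np.ndarray:
    """Index pairs of beads within the cutoff under periodic wrap."""
    if len(positions) == 0:
        return np.empty((0, 2), dtype=np.int64)
    wrapped = np.mod(positions, L)
    wrapped[wrapped >= L] = 0.0
    tree = cKDTree(wrapped, boxsize=L)
    return tree.query_pairs(cutoff, output_type="ndarray")


def _unwrap_component(positions: np.ndarray, adjacency: list[list[int]],
                      start: int, L: float) -> tuple[np.ndarray, bool]:
    """BFS unwrap of one connected bead cluster across periodic images.

    Returns unwrapped coordinates and a percolation flag (set when a
    bead is reachable through two inequivalent image paths).
    """
    n = len(positions)
    visited = np.zeros(n, dtype=bool)
    shift = np.zeros((n, 3))
    visited[start] = True
    queue = [start]
    percolates = False
    while queue:
        i = queue.pop()
        pi = positions[i] + shift[i]
        for j in adjacency[i]:
            dj = positions[j] - pi
            expected = -L * np.round(dj / L)
            if not visited[j]:
                shift[j] = expected
                visited[j] = True
                queue.append(j)
            elif np.any(np.abs(shift[j] - expected) > L / 2):
                # reached through two inequivalent image paths
                percolates = True
    return positions + shift, percolates


def find_micelles(configuration: Configuration, cutoff: float = 1.0,
                  tail_species: set[str] | frozenset[str] = frozenset({"C"}),
                  ethoxy_species: str = "E") -> MicelleSet:
    """Cluster surfactant molecules into micelles by tail-bead contact."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    tail_species = set(tail_species)
    if not tail_species:
        raise ValueError("tail species set must not be empty")
    species = np.asarray(configuration.species)
    mol = configuration.molecule_id
    tail_mask = np.isin(species, sorted(tail_species))
    tail_mols = np.unique(mol[tail_mask])
    if len(tail_mols) == 0:
        return MicelleSet(molecule_ids=np.empty(0, dtype=np.int64),
                          assignment=np.empty(0, dtype=np.int64),
                          sizes=np.empty(0, dtype=np.int64),
                          radii=np.empty(0),
                          percolating=np.empty(0, dtype=bool),
                          compositions=[])
    mol_index = {m: k for k, m in enumerate(tail_mols)}
    nmol = len(tail_mols)

    tail_idx = np.nonzero(tail_mask)[0]
    pairs = _tail_contact_pairs(configuration.positions[tail_idx],
                                configuration.box_edge, cutoff)
    # molecule-level contact graph
    mi = np.array([mol_index[mol[tail_idx[p]]] for p in pairs[:, 0]],
                  dtype=np.int64) if len(pairs) else np.empty(0, np.int64)
    mj = np.array([mol_index[mol[tail_idx[p]]] for p in pairs[:, 1]],
                  dtype=np.int64) if len(pairs) else np.empty(0, np.int64)
    graph = sparse.coo_matrix(
        (np.ones(len(mi)), (mi, mj)), shape=(nmol, nmol))
    n_clusters, labels = connected_components(graph, directed=False)

    sizes = np.bincount(labels, minlength=n_clusters).astype(np.int64)
    L = configuration.box_edge

    # per-cluster R_G over all beads of member molecules, BFS-unwrapped
    radii = np.zeros(n_clusters)
    percolating = np.zeros(n_clusters, dtype=bool)
    compositions: list[dict[int, int]] = []
    # per-molecule ethoxylation from its ethoxy bead count
    eth_count = {m: int(np.sum((mol == m) & (species == ethoxy_species)))
                 for m in tail_mols}
    surf_mask = np.isin(mol, tail_mols)
    for c in range(n_clusters):
        members = tail_mols[labels == c]
        bead_sel = np.nonzero(np.isin(mol, members) & surf_mask)[0]
        pos = configuration.positions[bead_sel]
        # adjacency: consecutive beads of a molecule + tail contacts
        local = {b: k for k, b in enumerate(bead_sel)}
        adj: list[list[int]] = [[] for _ in bead_sel]
        for k in range(len(bead_sel) - 1):
            if mol[bead_sel[k]] == mol[bead_sel[k + 1]]:
                adj[k].append(k + 1)
                adj[k + 1].append(k)
        for p, q in pairs:
            bp, bq = tail_idx[p], tail_idx[q]
            if bp in local and bq in local:
                adj[local[bp]].append(local[bq])
                adj[local[bq]].append(local[bp])
        unwrapped, perc = _unwrap_component(pos, adj, 0, L)
        extent = unwrapped.max(axis=0) - unwrapped.min(axis=0)
        percolating[c] = perc or bool(np.any(extent > L / 2))
        com = unwrapped.mean(axis=0)
        radii[c] = math.sqrt(float(((unwrapped - com) ** 2).sum(axis=1)
                                   .mean()))
        hist: dict[int, int] = {}
        for m in members:
            hist[eth_count[m]] = hist.get(eth_count[m], 0) + 1
        compositions.append(hist)

    return MicelleSet(molecule_ids=tail_mols, assignment=labels,
                      sizes=sizes, radii=radii, percolating=percolating,
                      compositions=compositions)


def aggregation_series(trajectory, cutoff: float = 1.0,
                       tail_species=frozenset({"C"}),
                       weighting: str = "number") -> np.ndarray:
    """Per-frame mean aggregation number N_agg."""
    frames = list(trajectory)
    if not frames:
        raise ValueError("trajectory must contain at least one frame")
    return np.array([
        find_micelles(f, cutoff, tail_species).aggregation_number(weighting)
        for f in frames])


def equilibration_point(series, block_span: float = 5000.0,
                        frame_interval: float | None = None,
                        times=None) -> int | None:
    """Earliest frame index from which block averages are stationary.

    The series is cut into blocks of ``block_span`` time units (frame
    spacing from ``times`` or ``frame_interval``).  The run counts as
    equilibrated from the first block whose own and all subsequent
    block means lie within one pooled (within-block) standard deviation
    of their joint mean.  Returns the start frame of that block, or
    ``None`` when no such block exists ("not equilibrated").
    """
    series = np.asarray(series, dtype=float)
    if times is not None:
        times = np.asarray(times, dtype=float)
        if len(times) != len(series):
            raise ValueError("times and series lengths differ")
        frame_interval = float(np.median(np.diff(times))) if len(times) > 1 \
            else block_span
    if frame_interval is None:
        frame_interval = 1.0
    per_block = max(int(round(block_span / frame_interval)), 1)
    n_blocks = len(series) // per_block
    if n_blocks < 3:
        raise ValueError(
            f"need at least 3 full blocks ({3 * per_block} frames), "
            f"got {len(series)}")
    blocks = series[:n_blocks * per_block].reshape(n_blocks, per_block)
    means = blocks.mean(axis=1)
    variances = blocks.var(axis=1, ddof=1) if per_block > 1 \
        else np.zeros(n_blocks)
    for b in range(n_blocks - 1):
        mu = means[b:].mean()
        pooled = math.sqrt(float(variances[b:].mean()))
        if np.all(np.abs(means[b:] - mu) <= pooled):
            return b * per_block
    return None


def radius_of_gyration(member_positions, box: float) -> tuple[float, bool]:
    """R_G of one bead cluster with periodic unwrapping.

    Beads are unwrapped by minimum-image chaining against the running
    centroid, which is exact for clusters smaller than half the box.
    Returns ``(R_G, percolating)``; the flag warns that the cluster
    spans more than L/2 in some direction, where R_G is ill-defined.
    """
    pos = np.asarray(member_positions, dtype=float)
    if pos.ndim != 2 or len(pos) == 0:
        raise ValueError("member_positions must be a non-empty (n, 3) array")
    L = float(box)
    unwrapped = np.empty_like(pos)
    unwrapped[0] = pos[0]
    centroid = pos[0].copy()
    for k in range(1, len(pos)):
        d = pos[k] - centroid
        d -= L * np.round(d / L)
        unwrapped[k] = centroid + d
        centroid = unwrapped[:k + 1].mean(axis=0)
    extent = unwrapped.max(axis=0) - unwrapped.min(axis=0)
    percolating = bool(np.any(extent > L / 2))
    com = unwrapped.mean(axis=0)
    rg = math.sqrt(float(((unwrapped - com) ** 2).sum(axis=1).mean()))
    return rg, percolating


def sphere_radius(R_G: float) -> float:
    """Equivalent uniform-sphere radius, R_S = sqrt(5/3) R_G."""
    if R_G < 0:
        raise ValueError("R_G must be >= 0")
    return math.sqrt(5.0 / 3.0) * R_G


@dataclass
class SphericityProfile:
    """Binned R_G^3/N profile and its quadratic-fit minimum."""

    bin_centers: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    counts: np.ndarray
    n_star: float | None
    rg_star: float | None
    minimum_defined: bool
    reason: str = ""


def sphericity_profile(micelle_sets, bin_width: int = 5,
                       min_count: int = 1) -> SphericityProfile:
    """Pool micelles and profile R_G^3/N against N in bins of width 5.

    The most-spherical aggregation number N* is the vertex of a
    quadratic through the lowest bin and its two neighbours; a flat or
    non-convex profile leaves the minimum undefined.
    """
    Ns: list[int] = []
    ys: list[float] = []
    for ms in micelle_sets:
        for s, r in zip(ms.sizes, ms.radii):
            Ns.append(int(s))
            ys.append(r ** 3 / s)
    if not Ns:
        raise ValueError("no micelles supplied")
    Ns = np.array(Ns)
    ys = np.array(ys)
    idx = Ns // bin_width
    present = np.unique(idx)
    centers, means, sds, counts = [], [], [], []
    for b in present:
        sel = idx == b
        if sel.sum() < min_count:
            continue
        centers.append((b + 0.5) * bin_width)
        means.append(ys[sel].mean())
        sds.append(ys[sel].std(ddof=1) if sel.sum() > 1 else 0.0)
        counts.append(int(sel.sum()))
    centers = np.array(centers)
    means = np.array(means)
    sds = np.array(sds)
    counts = np.array(counts)

    prof = dict(bin_centers=centers, means=means, sds=sds, counts=counts)
    if len(centers) < 3:
        return SphericityProfile(**prof, n_star=None, rg_star=None,
                                 minimum_defined=False,
                                 reason="fewer than 3 populated bins")
    if means.max() - means.min() < 1e-9 * max(abs(means).max(), 1e-30):
        return SphericityProfile(**prof, n_star=None, rg_star=None,
                                 minimum_defined=False,
                                 reason="profile is flat")
    k = int(np.argmin(means))
    if k == 0 or k == len(centers) - 1:
        return SphericityProfile(**prof, n_star=None, rg_star=None,
                                 minimum_defined=False,
                                 reason="minimum at profile edge")
    x = centers[k - 1:k + 2]
    y = means[k - 1:k + 2]
    a, b, c = np.polyfit(x, y, 2)
    if a <= 0:
        return SphericityProfile(**prof, n_star=None, rg_star=None,
                                 minimum_defined=False,
                                 reason="profile not convex at minimum")
    n_star = -b / (2 * a)
    y_star = np.polyval([a, b, c], n_star)
    rg_star = (max(y_star, 0.0) * n_star) ** (1.0 / 3.0)
    return SphericityProfile(**prof, n_star=float(n_star),
                             rg_star=float(rg_star), minimum_defined=True)


def composition_mixing(micelle_set: MicelleSet, global_distribution,
                       n_null: int = 2000, seed: int = 0) -> "np.ndarray":
    """Per-micelle composition-mixing test against the global n mixture.

    For each micelle the Pearson chi-squared distance between its
    ethoxylation histogram and the global weights is computed, together
    with its quantile under the multinomial null (micelle size as the
    draw count, Monte-Carlo calibrated).  Quantiles near 1 flag
    micelles that are compositionally segregated.

    Returns a structured array with fields ``statistic`` and
    ``quantile``.
    """
    weights = dict(global_distribution.weights) \
        if hasattr(global_distribution, "weights") else dict(global_distribution)
    support = sorted(weights)
    p = np.array([weights[k] for k in support], dtype=float)
    p = p / p.sum()
    if np.sum(p > 0) < 2:
        raise ValueError("composition mixing is meaningless for a "
                         "monodisperse system")
    rng = np.random.default_rng(seed)
    out = np.zeros(micelle_set.n_micelles,
                   dtype=[("statistic", float), ("quantile", float)])

    def stat(counts: np.ndarray) -> float:
        n = counts.sum()
        expected = n * p
        keep = expected > 0
        return float(((counts[keep] - expected[keep]) ** 2
                      / expected[keep]).sum())

    null_cache: dict[int, np.ndarray] = {}
    for c, hist in enumerate(micelle_set.compositions):
        counts = np.array([hist.get(k, 0) for k in support], dtype=float)
        s = stat(counts)
        n = int(counts.sum())
        if n not in null_cache:
            draws = rng.multinomial(n, p, size=n_null)
            exp = n * p
            keep = exp > 0
            null_cache[n] = (((draws[:, keep] - exp[keep]) ** 2
                              / exp[keep]).sum(axis=1))
        null = null_cache[n]
        out["statistic"][c] = s
        out["quantile"][c] = float((null <= s + 1e-12).mean())
    return out
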