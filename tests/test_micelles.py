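"""Micelle clustering, aggregation statistics and shape analysis."""

import numpy as np
import pytest

from mesodpd import (EthoxylationDistribution, aggregation_series,
                     composition_mixing, equilibration_point, find_micelles,
                     make_micelle_field, radius_of_gyration, sphere_radius,
                     sphericity_profile)
from mesodpd.micelles import MicelleSet
from mesodpd.system import Configuration


def brute_force_partition(cfg, cutoff, tail_species={"C"}):
    """All-pairs union-find oracle over molecules."""
    species = np.asarray(cfg.species)
    mask = np.isin(species, sorted(tail_species))
    mols = np.unique(cfg.molecule_id[mask])
    parent = {m: m for m in mols}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    idx = np.nonzero(mask)[0]
    L = cfg.box_edge
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            d = cfg.positions[idx[i]] - cfg.positions[idx[j]]
            d -= L * np.round(d / L)
            if np.linalg.norm(d) < cutoff:
                a, b = find(cfg.molecule_id[idx[i]]), \
                    find(cfg.molecule_id[idx[j]])
                if a != b:
                    parent[a] = b
    groups = {}
    for m in mols:
        groups.setdefault(find(m), set()).add(m)
    return sorted(frozenset(g) for g in groups.values())


class TestFindMicelles:
    def test_two_separated_micelles_recovered_exactly(self, ff):
        cfg, truth = make_micelle_field([30, 30], box_edge=22.0, seed=2,
                                        force_field=ff)
        ms = find_micelles(cfg, 1.0, ff.tail_species())
        assert sorted(ms.sizes) == [30, 30]
        assert ms.sizes.sum() == 60

    def test_lone_molecule_is_cluster_of_one(self, ff):
        cfg, _ = make_micelle_field([1], box_edge=10.0, seed=3,
                                    force_field=ff)
        ms = find_micelles(cfg, 1.0, ff.tail_species())
        assert list(ms.sizes) == [1]

    def test_no_surfactant_gives_empty_set(self, ff):
        n = 50
        rng = np.random.default_rng(0)
        cfg = Configuration(rng.uniform(0, 5, (n, 3)), np.zeros((n, 3)),
                            np.array(["W"] * n), np.arange(n), 5.0)
        ms = find_micelles(cfg, 1.0, ff.tail_species())
        assert ms.n_micelles == 0

    def test_matches_brute_force_union_find(self, ff):
        # a crowded random arrangement exercises nontrivial merges
        cfg, _ = make_micelle_field([10, 8, 7, 12, 13], box_edge=26.0,
                                    seed=5, force_field=ff, fill_water=False)
        rng = np.random.default_rng(1)
        cfg.positions += rng.normal(0, 0.8, cfg.positions.shape)
        cfg.wrap()
        ms = find_micelles(cfg, 1.0, ff.tail_species())
        got = {}
        for m, lab in zip(ms.molecule_ids, ms.assignment):
            got.setdefault(lab, set()).add(m)
        assert sorted(frozenset(g) for g in got.values()) == \
            brute_force_partition(cfg, 1.0)

    def test_invariant_under_translation_and_wrap(self, ff):
        cfg, _ = make_micelle_field([15, 20], box_edge=18.0, seed=6,
                                    force_field=ff)
        ms1 = find_micelles(cfg, 1.0, ff.tail_species())
        shifted = cfg.copy()
        shifted.positions += np.array([3.7, -2.2, 9.9])
        shifted.wrap()
        ms2 = find_micelles(shifted, 1.0, ff.tail_species())
        assert sorted(ms1.sizes) == sorted(ms2.sizes)
        assert np.allclose(np.sort(ms1.radii), np.sort(ms2.radii), atol=1e-9)


class TestAggregationSeries:
    def test_static_trajectory_constant(self, ff):
        cfg, _ = make_micelle_field([30, 30], box_edge=22.0, seed=2,
                                    force_field=ff)
        series = aggregation_series([cfg, cfg, cfg],
                                    tail_species=ff.tail_species())
        assert np.allclose(series, 30.0)

    def test_merge_doubles_aggregation_number(self, ff):
        apart, _ = make_micelle_field([20, 20], box_edge=22.0, seed=4,
                                      force_field=ff, fill_water=False)
        merged = apart.copy()
        # slam the two micelles together: collapse all tails pairwise
        ms = find_micelles(apart, 1.0, ff.tail_species())
        mols0 = ms.molecule_ids[ms.assignment == 0]
        sel = np.isin(merged.molecule_id, mols0)
        other = ~sel
        delta = merged.positions[other][:1] - merged.positions[sel][:1]
        merged.positions[sel] += delta
        merged.wrap()
        series = aggregation_series([apart, merged],
                                    tail_species=ff.tail_species())
        assert series[0] == pytest.approx(20.0)
        assert series[1] == pytest.approx(40.0)

    def test_mass_weighting_option(self):
        ms = MicelleSet(molecule_ids=np.arange(30),
                        assignment=np.r_[np.zeros(10), np.ones(20)],
                        sizes=np.array([10, 20]), radii=np.zeros(2),
                        percolating=np.zeros(2, bool),
                        compositions=[{0: 10}, {0: 20}])
        assert ms.aggregation_number() == 15.0
        assert ms.aggregation_number("mass") == pytest.approx(
            (100 + 400) / 30)


class TestEquilibration:
    def test_constant_series_equilibrated_from_start(self):
        assert equilibration_point(np.full(300, 5.0), 5000.0,
                                   frame_interval=50.0) == 0

    def test_monotone_ramp_never_equilibrates(self):
        series = np.linspace(0, 10, 300)
        assert equilibration_point(series, 5000.0,
                                   frame_interval=50.0) is None

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError, match="blocks"):
            equilibration_point(np.ones(100), 5000.0, frame_interval=50.0)

    def test_changepoint_detection_calibration(self):
        # small version of the seeded replicate study (full study in the
        # acceptance suite): detection within one block in >= 90%
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            t = np.arange(1000) * 50.0
            t_star = 20000.0
            signal = np.where(t < t_star, 10.0 * t / t_star, 10.0)
            series = signal + rng.normal(0, 1.0, len(t))
            got = equilibration_point(series, 5000.0, frame_interval=50.0)
            if got is None:
                continue
            true_block = int(t_star / 5000.0)
            if abs(got // 100 - true_block) <= 1:
                hits += 1
        assert hits / reps >= 0.90


class TestRadiusOfGyration:
    def test_single_and_pair(self):
        assert radius_of_gyration([[1.0, 1.0, 1.0]], 10.0)[0] == 0.0
        rg, perc = radius_of_gyration([[1.0, 0, 0], [3.0, 0, 0]], 10.0)
        assert rg == pytest.approx(1.0)
        assert not perc

    def test_uniform_sphere_moment(self, rng):
        R = 2.0
        u = rng.normal(size=(10_000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = R * rng.uniform(size=(10_000, 1)) ** (1 / 3)
        pts = 10.0 + u * r  # centred mid-box
        rg, perc = radius_of_gyration(pts, 20.0)
        assert rg == pytest.approx(np.sqrt(3.0 / 5.0) * R, rel=0.01)
        assert sphere_radius(rg) == pytest.approx(R, rel=0.01)

    def test_unwraps_cluster_straddling_boundary(self):
        pts = np.array([[9.8, 5.0, 5.0], [0.1, 5.0, 5.0]])
        rg, perc = radius_of_gyration(pts, 10.0)
        assert rg == pytest.approx(0.15)
        assert not perc

    def test_percolating_cluster_flagged(self):
        pts = np.stack([np.linspace(0, 9.5, 20),
                        np.full(20, 5.0), np.full(20, 5.0)], axis=1)
        rg, perc = radius_of_gyration(pts, 10.0)
        assert perc

    def test_sphere_radius_values(self):
        assert sphere_radius(0.0) == 0.0
        assert sphere_radius(np.sqrt(3.0 / 5.0)) == pytest.approx(1.0)


def _fake_set(sizes, radii):
    sizes = np.asarray(sizes)
    return MicelleSet(molecule_ids=np.arange(sizes.sum()),
                      assignment=np.repeat(np.arange(len(sizes)), sizes),
                      sizes=sizes, radii=np.asarray(radii),
                      percolating=np.zeros(len(sizes), bool),
                      compositions=[{0: int(s)} for s in sizes])


class TestSphericityProfile:
    def test_exactly_spherical_population_has_no_minimum(self):
        sizes = np.repeat(np.arange(10, 100, 5), 4)
        radii = (2.0 * sizes) ** (1 / 3)  # R_G^3 = 2 N exactly
        prof = sphericity_profile([_fake_set(sizes, radii)])
        assert not prof.minimum_defined

    def test_parabolic_minimum_located_within_one_bin(self):
        rng = np.random.default_rng(3)
        sizes = rng.integers(20, 100, 600)
        y = 3.0 + 0.002 * (sizes - 55.0) ** 2
        radii = (y * sizes) ** (1 / 3)
        prof = sphericity_profile([_fake_set(sizes, radii)])
        assert prof.minimum_defined
        assert abs(prof.n_star - 55.0) <= 5.0

    def test_single_bin_reports_undefined(self):
        prof = sphericity_profile([_fake_set([21, 22, 23], [2., 2., 2.])])
        assert not prof.minimum_defined
        assert "bins" in prof.reason


class TestCompositionMixing:
    def test_multinomial_micelles_are_calibrated(self):
        rng = np.random.default_rng(8)
        dist = EthoxylationDistribution({0: 0.52, 1: 0.28, 2: 0.12, 3: 0.08})
        p = [dist.weights[k] for k in dist.support]
        sizes = rng.integers(20, 80, 300)
        comps = [dict(zip(dist.support, rng.multinomial(s, p)))
                 for s in sizes]
        ms = MicelleSet(molecule_ids=np.arange(sizes.sum()),
                        assignment=np.repeat(np.arange(len(sizes)), sizes),
                        sizes=sizes, radii=np.zeros(len(sizes)),
                        percolating=np.zeros(len(sizes), bool),
                        compositions=comps)
        res = composition_mixing(ms, dist, seed=1)
        frac = (res["quantile"] > 0.95).mean()
        assert 0.01 < frac < 0.12  # ~5% exceed the 95% null quantile

    def test_segregated_micelle_is_extreme(self):
        dist = EthoxylationDistribution({0: 0.52, 1: 0.28, 2: 0.12, 3: 0.08})
        ms = _fake_set([40], [2.0])
        ms.compositions = [{3: 40}]  # only n=3 molecules
        res = composition_mixing(ms, dist, seed=2)
        assert res["quantile"][0] > 0.999

    def test_size_one_micelle_defined(self):
        dist = EthoxylationDistribution({0: 0.5, 1: 0.5})
        ms = _fake_set([1], [0.0])
        ms.compositions = [{0: 1}]
        res = composition_mixing(ms, dist, seed=3)
        assert np.isfinite(res["quantile"][0])

    def test_monodisperse_rejected(self):
        dist = {0: 1.0}
        ms = _fake_set([10], [1.0])
        with pytest.raises(ValueError, match="monodisperse"):
            composition_mixing(ms, dist)
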