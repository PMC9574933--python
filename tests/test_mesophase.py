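"""Mesophase periodicity: directors, spacings, catalogs, classification."""

import itertools
import math

import numpy as np
import pytest

from mesodpd import (allowed_d_spacings, allowed_r_s, analyze_hexagonal,
                     analyze_lamellar, classify_phase, d_spacing,
                     fit_d_model, fit_hexagonal_lattice,
                     interpolate_ethoxylation, lamellar_director, layer_count,
                     make_hexagonal, make_lamellar, make_micelle_field)
from mesodpd.mesophase import PhaseAnalysisError, gauss_reduce, round_sf
from mesodpd.system import Configuration


def chain_config(directions, L=20.0, beads=5, l0=0.6, seed=0):
    """Molecules as straight chains along the given unit vectors."""
    rng = np.random.default_rng(seed)
    pos, spc, mol = [], [], []
    for m, u in enumerate(directions):
        start = rng.uniform(0, L, 3)
        for k in range(beads):
            pos.append(start + k * l0 * np.asarray(u))
            spc.append("C" if k < beads - 1 else "S")
            mol.append(m)
    pos = np.array(pos)
    return Configuration(pos, np.zeros_like(pos), np.array(spc),
                         np.array(mol), L)


class TestDirector:
    def test_aligned_molecules_give_axis(self):
        cfg = chain_config([[0, 0, 1]] * 20)
        d = lamellar_director(cfg)
        assert np.allclose(np.abs(d), [0, 0, 1], atol=1e-9)

    def test_antiparallel_mixture_is_nematic(self):
        dirs = [[0, 0, 1]] * 10 + [[0, 0, -1]] * 10
        d = lamellar_director(chain_config(dirs))
        assert np.allclose(np.abs(d), [0, 0, 1], atol=1e-9)
        assert d[2] > 0  # canonical sign

    def test_isotropic_returns_none(self):
        # exactly isotropic orientation set: the 6 signed axis vectors
        axes = [[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        assert lamellar_director(chain_config(axes * 10, seed=2)) is None

    def test_tilted_stack_recovered_within_a_degree(self, ff):
        cfg, truth = make_lamellar(40.0, kappa=(0, 2, 4), seed=9,
                                   noise_sigma=0.1, force_field=ff)
        d = lamellar_director(cfg)
        cosang = abs(float(d @ truth["director"]))
        assert math.degrees(math.acos(min(cosang, 1.0))) < 1.0


class TestLayerCountAndSpacing:
    def test_straight_and_tilted_fixtures(self, ff):
        cfg, truth = make_lamellar(40.0, kappa=5, seed=10, force_field=ff)
        lm = analyze_lamellar(cfg)
        assert lm.kappa == 5
        assert lm.d == pytest.approx(8.0, rel=1e-3)

        cfg8, t8 = make_lamellar(40.0, kappa=(0, 3, 8), seed=11,
                                 noise_sigma=0.1, force_field=ff)
        lm8 = analyze_lamellar(cfg8)
        assert lm8.kappa == 8
        assert lm8.d == pytest.approx(t8["d"], rel=0.01)

    def test_uniform_positions_rejected(self, ff):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(300, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        cfg = chain_config(np.broadcast_to([0, 0, 1.0], (300, 3)), L=30.0,
                           seed=3)
        cfg.positions[:] = rng.uniform(0, 30.0, cfg.positions.shape)
        with pytest.raises(PhaseAnalysisError):
            layer_count(cfg, np.array([0, 0, 1.0]))

    def test_d_spacing_formula(self):
        assert d_spacing(40.0, 0.0, 5) == pytest.approx(8.0)
        assert d_spacing(40.0, 60.0, 2) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            d_spacing(40.0, 95.0, 2)

    def test_incommensurate_tilt_recovered_when_flagged(self, ff):
        # 25.8 degrees with 4 layers: d = 40 cos(25.8)/4 ~ 9.0
        kz = 4.0
        kx = kz * math.tan(math.radians(25.8))
        cfg, truth = make_lamellar(40.0, kappa=(kx, 0, kz), seed=12,
                                   noise_sigma=0.05,
                                   allow_incommensurate=True,
                                   force_field=ff)
        lm = analyze_lamellar(cfg)
        assert lm.d == pytest.approx(40 * math.cos(math.radians(25.8)) / 4,
                                     rel=0.01)


class TestAllowedDSpacings:
    def test_contains_axis_aligned_and_oblique_entries(self):
        cat = allowed_d_spacings(40.0, 5.0, 12.0)
        assert 10.0 in cat                       # (4, 0, 0)
        assert round_sf(40 / math.sqrt(17)) in cat  # (4, 1, 0)

    def test_values_decrease_with_index_norm(self):
        cat = allowed_d_spacings(40.0, 4.0, 12.0)
        norms = [sum(k ** 2 for k in idx) for idx in cat.indices]
        assert np.all(np.diff(norms) >= 0)
        assert np.all(np.diff(cat.values) < 0)

    def test_matches_brute_force_enumeration(self):
        L, dmin, dmax = 17.0, 3.0, 9.0
        brute = set()
        for kx, ky, kz in itertools.product(range(7), repeat=3):
            if kx == ky == kz == 0:
                continue
            d = L / math.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
            if dmin <= d <= dmax:
                brute.add(round_sf(d))
        assert set(allowed_d_spacings(L, dmin, dmax).values.tolist()) == brute

    def test_empty_range(self):
        assert len(allowed_d_spacings(40.0, 41.0, 50.0)) == 0


class TestHexagonalLattice:
    def test_perfect_lattice_three_equal_distances(self):
        # commensurate near-hexagonal cell: a=(10,0), b=(5, 10): reduced
        s = 10.0
        pts = []
        a, b = np.array([s, 0.0]), np.array([s / 2, s])
        for i in range(8):
            for j in range(8):
                pts.append((i * a + j * b) % 40.0)
        pts = np.unique(np.round(pts, 6) % 40.0, axis=0)
        m = fit_hexagonal_lattice(pts, 40.0)
        assert m.r_s == pytest.approx(np.mean(m.lengths))

    def test_printed_mixed_cell_average(self):
        a, b = np.array([10.0, 0.0]), np.array([4.0, 8.0])
        pts = []
        for i in range(-6, 7):
            for j in range(-6, 7):
                pts.append(tuple(np.round((i * a + j * b) % 40.0, 6) % 40.0))
        pts = np.array(sorted(set(pts)))
        m = fit_hexagonal_lattice(pts, 40.0)
        expected = (10 + math.sqrt(80) + 10) / 3
        assert m.r_s == pytest.approx(expected, rel=1e-9)
        assert round_sf(m.r_s) == 9.65

    def test_noise_robustness(self):
        a, b = np.array([10.0, 0.0]), np.array([4.0, 8.0])
        pts = np.array(sorted({tuple(np.round((i * a + j * b) % 40.0, 6)
                                     % 40.0)
                               for i in range(-6, 7) for j in range(-6, 7)}))
        rng = np.random.default_rng(4)
        noisy = (pts + rng.normal(0, 0.2, pts.shape)) % 40.0
        m = fit_hexagonal_lattice(noisy, 40.0)
        assert m.r_s == pytest.approx(9.648, rel=0.02)

    def test_invariant_under_relabeling_and_translation(self):
        a, b = np.array([10.0, 0.0]), np.array([4.0, 8.0])
        pts = np.array(sorted({tuple(np.round((i * a + j * b) % 40.0, 6)
                                     % 40.0)
                               for i in range(-6, 7) for j in range(-6, 7)}))
        rng = np.random.default_rng(9)
        shuffled = (pts[rng.permutation(len(pts))]
                    + np.array([3.3, -7.7])) % 40.0
        m = fit_hexagonal_lattice(shuffled, 40.0)
        assert m.r_s == pytest.approx((20 + math.sqrt(80)) / 3, rel=1e-9)

    def test_incommensurate_centres_flagged(self):
        rng = np.random.default_rng(10)
        pts = rng.uniform(0, 40.0, (12, 2))
        m = fit_hexagonal_lattice(pts, 40.0)
        assert not m.commensurate
        assert m.residual > 0.5


class TestAllowedRs:
    def test_matches_bounded_integer_matrix_scan(self):
        # oracle: scan all integer matrices with |I| <= 12
        L, dco = 40.0, 1.5
        brute = set()
        for i1, i2, i3, i4 in itertools.product(range(-12, 13), repeat=4):
            det = i1 * i4 - i2 * i3
            if det == 0:
                continue
            a = np.array([L * i4 / det, -L * i2 / det])
            b = np.array([-L * i3 / det, L * i1 / det])
            a, b = gauss_reduce(a, b)
            ls = sorted([np.linalg.norm(a), np.linalg.norm(b),
                         np.linalg.norm(a - b)])
            if ls[2] - ls[0] > dco:
                continue
            rs = sum(ls) / 3
            if 7.5 < rs < 11.0:
                brute.add(round_sf(rs))
        cat = allowed_r_s(L, dco, 7.5, 11.0)
        assert set(cat.values.tolist()) == brute

    def test_perfect_cells_appear_for_commensurate_boxes(self):
        # L = 4 * 10: the |a| = 10 axis-aligned near-hexagonal cell
        cat = allowed_r_s(40.0, 1.5, 7.5, 11.0)
        entry = [d for d in cat.details
                 if any(abs(x - 10.0) < 1e-9 for x in d["lengths"])]
        assert entry, "no cell with a lattice vector of magnitude 10"

    def test_fixture_recovery_within_catalog(self, ff):
        cfg, truth = make_hexagonal(40.0, a=[10, 0], b=[4, 8], seed=13,
                                    noise_sigma=0.1, force_field=ff)
        m = analyze_hexagonal(cfg)
        assert round_sf(m.r_s) in allowed_r_s(40.0, 1.5, 7.5, 11.0)


class TestClassification:
    def test_fixture_labels(self, ff):
        mic, _ = make_micelle_field([25, 30], box_edge=20.0, seed=14,
                                    force_field=ff)
        assert classify_phase(mic) == "micellar"
        hexa, _ = make_hexagonal(40.0, a=[10, 0], b=[4, 8], seed=15,
                                 force_field=ff)
        assert classify_phase(hexa) == "hexagonal"
        lam, _ = make_lamellar(40.0, kappa=5, seed=16, force_field=ff)
        assert classify_phase(lam) == "lamellar-perfect"

    def test_bridged_stack_is_imperfect(self, ff):
        frames, truth = make_lamellar(40.0, kappa=5, seed=17, n_frames=8,
                                      bridge_rate=0.6, force_field=ff)
        assert any(truth["bridged_frames"])
        assert classify_phase(frames) == "lamellar-imperfect"


class TestConcentrationModel:
    def test_exact_recovery_of_layer_thickness(self):
        volumes = {"V_s": 3.2, "V_I": 0.55, "V_w": 0.52}
        d_s = 6.0
        d_obs, counts = {}, {}
        for c, (ns, ni, nw) in {60: (500, 500, 2000), 70: (600, 600, 1200),
                                80: (700, 700, 600)}.items():
            x = (ns * volumes["V_s"] + ni * volumes["V_I"]
                 + nw * volumes["V_w"]) / (ns * volumes["V_s"])
            d_obs[c] = d_s * x
            counts[c] = (ns, ni, nw)
        got, residuals = fit_d_model(d_obs, counts, volumes)
        assert got == pytest.approx(6.0, abs=0.01)
        assert all(abs(r) < 1e-9 for r in residuals.values())

    def test_pure_surfactant_limit(self):
        volumes = {"V_s": 2.0, "V_I": 0.5, "V_w": 0.5}
        counts = {c: (100, 0, 0) for c in (1, 2, 3)}
        d_obs = {c: 7.5 for c in counts}
        d_s, _ = fit_d_model(d_obs, counts, volumes)
        assert d_s == pytest.approx(7.5)

    def test_volume_scale_invariance(self):
        counts = {c: (100, 100, 400) for c in (1, 2, 3)}
        v1 = {"V_s": 3.0, "V_I": 0.5, "V_w": 0.5}
        v2 = {k: 2 * v for k, v in v1.items()}
        d_obs = {c: 9.0 for c in counts}
        assert fit_d_model(d_obs, counts, v1)[0] == \
            pytest.approx(fit_d_model(d_obs, counts, v2)[0])

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_d_model({1: 8.0, 2: 7.0}, {1: (1, 0, 0), 2: (1, 0, 0)},
                        {"V_s": 1, "V_I": 1, "V_w": 1})


class TestInterpolation:
    @pytest.mark.parametrize("d_poly,expected",
                             [(8.0, 0.0), (9.0, 1.0), (8.5, 0.5)])
    def test_endpoints_and_midpoint(self, d_poly, expected):
        assert interpolate_ethoxylation(8.0, 9.0, d_poly) == \
            pytest.approx(expected)

    def test_equal_monodisperse_spacings_rejected(self):
        with pytest.raises(ValueError):
            interpolate_ethoxylation(8.0, 8.0, 8.5)
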