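"""Pair force laws, bonded terms and the dual-route force evaluation."""

import math

import numpy as np
import pytest

from mesodpd import (angle_force, bond_force, compute_forces,
                     conservative_force, pair_thermostat_forces)
from mesodpd.forces import angle_energy
from mesodpd.system import Configuration
from mesodpd._kernels import pair_normal


class TestConservativeForce:
    def test_zero_at_cutoff_and_beyond(self):
        assert np.allclose(conservative_force([1.0, 0, 0], 25.0, 1.0), 0)
        assert np.allclose(conservative_force([0, 1.5, 0], 25.0, 1.0), 0)

    def test_maximum_repulsion_near_contact(self):
        f = conservative_force([1e-9, 0, 0], 25.0, 1.0)
        assert np.linalg.norm(f) == pytest.approx(25.0, rel=1e-6)

    def test_linear_in_separation(self):
        f = conservative_force([0.5, 0, 0], 30.0, 1.0)
        assert f[0] == pytest.approx(15.0)
        f2 = conservative_force([0, 0, 0.55], 30.0, 1.1)
        assert f2[2] == pytest.approx(15.0)

    def test_coincident_beads_random_direction(self):
        f = conservative_force([0, 0, 0], 25.0, 1.0, rng_seed=3)
        assert np.linalg.norm(f) == pytest.approx(25.0)


class TestThermostatPair:
    def test_zero_beyond_cutoff(self):
        d, r = pair_thermostat_forces([2.0, 0, 0], [1, 1, 1], 4.5, 3.0,
                                      1.0, 0.01, 0.7)
        assert np.allclose(d, 0) and np.allclose(r, 0)

    def test_dissipative_vanishes_for_transverse_motion(self):
        d, r = pair_thermostat_forces([0.5, 0, 0], [0, 1.0, 0], 4.5, 3.0,
                                      1.0, 0.01, 0.0)
        assert np.allclose(d, 0)

    def test_weight_functions_and_scaling(self):
        d, r = pair_thermostat_forces([0.5, 0, 0], [1.0, 0, 0], 4.5, 3.0,
                                      1.0, 0.01, 1.0)
        w = 0.5
        assert d[0] == pytest.approx(-4.5 * w * w * 1.0)
        assert r[0] == pytest.approx(3.0 * w / math.sqrt(0.01))

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            pair_thermostat_forces([0.5, 0, 0], [0, 0, 0], 4.5, 3.0,
                                   1.0, 0.0, 0.0)

    def test_counter_noise_symmetric_and_centred(self):
        zs = np.array([pair_normal(1, 5, 2 * k, 2 * k + 1)
                       for k in range(100_000)])
        assert pair_normal(1, 5, 10, 11) == pair_normal(1, 5, 11, 10)
        # mean within 4 standard errors, unit variance within 2%
        assert abs(zs.mean()) < 4 / math.sqrt(len(zs))
        assert abs(zs.std() - 1.0) < 0.02


class TestBondForce:
    def test_zero_at_rest_length(self):
        f, u = bond_force(0.6, 0.6, 150.0)
        assert f == 0.0 and u == 0.0

    def test_linear_restoring_matches_gradient(self):
        C, l0 = 150.0, 0.6
        for r in (0.4, 0.65, 0.9):
            f, _ = bond_force(r, l0, C)
            h = 1e-7
            up = bond_force(r + h, l0, C)[1]
            dn = bond_force(r - h, l0, C)[1]
            assert f == pytest.approx(-(up - dn) / (2 * h), rel=1e-5)
        assert bond_force(0.7, l0, C)[0] == pytest.approx(-C * 0.1)

    def test_energy_symmetric_about_minimum(self):
        assert bond_force(0.5, 0.6, 150.0)[1] == \
            pytest.approx(bond_force(0.7, 0.6, 150.0)[1])


class TestAngleForce:
    def test_straight_chain_at_equilibrium_gives_zero(self):
        fi, fj, fk = angle_force([0, 0, 0], [1, 0, 0], [2, 0, 0], 180.0, 5.0)
        assert np.allclose(fi, 0) and np.allclose(fj, 0) and np.allclose(fk, 0)

    def test_matches_numerical_gradient_at_150_degrees(self):
        pj = np.zeros(3)
        pi = np.array([1.0, 0.0, 0.0])
        ang = math.radians(150.0)
        pk = np.array([math.cos(ang), math.sin(ang), 0.0])
        fi, fj, fk = angle_force(pi, pj, pk, 180.0, 5.0)
        h = 1e-6
        for point, force in ((pi, fi), (pj, fj), (pk, fk)):
            for dim in range(3):
                dp = np.zeros(3)
                dp[dim] = h
                args = [pi.copy(), pj.copy(), pk.copy()]
                idx = [id(pi), id(pj), id(pk)].index(id(point))
                args[idx] = point + dp
                up = angle_energy(*args, 180.0, 5.0)
                args[idx] = point - dp
                dn = angle_energy(*args, 180.0, 5.0)
                assert force[dim] == pytest.approx(-(up - dn) / (2 * h),
                                                   abs=1e-6)

    def test_net_force_and_torque_vanish(self):
        pi = np.array([0.3, 0.1, -0.2])
        pj = np.array([1.0, 0.0, 0.3])
        pk = np.array([1.8, 0.7, 0.1])
        fi, fj, fk = angle_force(pi, pj, pk, 180.0, 5.0)
        assert np.allclose(fi + fj + fk, 0, atol=1e-12)
        torque = (np.cross(pi, fi) + np.cross(pj, fj) + np.cross(pk, fk))
        assert np.allclose(torque, 0, atol=1e-12)


class TestWholeSystemForces:
    def _random_config(self, n, L, seed):
        rng = np.random.default_rng(seed)
        return Configuration(
            positions=rng.uniform(0, L, (n, 3)),
            velocities=rng.normal(size=(n, 3)),
            species=np.array(["W"] * n),
            molecule_id=np.arange(n),
            box_edge=L)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cell_list_equals_brute_force(self, ff, seed):
        cfg = self._random_config(200, 5.0, seed)
        fb = compute_forces(cfg, ff, method="brute", seed=seed, step=3)
        fc = compute_forces(cfg, ff, method="cells", seed=seed, step=3)
        assert np.abs(fb.total - fc.total).max() < 1e-12 * max(
            1.0, np.abs(fb.total).max())

    def test_newtons_third_law_total_force_zero(self, ff):
        cfg = self._random_config(150, 5.0, 5)
        fb = compute_forces(cfg, ff, seed=5, step=1)
        assert np.abs(fb.total.sum(axis=0)).max() < 1e-10

    def test_sheared_evaluation_matches_brute(self, ff):
        cfg = self._random_config(200, 5.0, 8)
        cfg.shear_offset = 1.7
        cfg.shear_rate = 0.05
        fb = compute_forces(cfg, ff, method="brute", seed=8, step=2)
        fc = compute_forces(cfg, ff, method="cells", seed=8, step=2)
        assert np.abs(fb.total - fc.total).max() < 1e-12 * max(
            1.0, np.abs(fb.total).max())
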