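"""Unit system, SI mapping and force-field registry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesodpd import (ForceFieldError, bond_length, build_unit_map, convert,
                     gamma_from_sigma, load_force_field, sigma_from_gamma)
from mesodpd.forcefield import bead_volume_from_cutoff, coupling_from_unit_map


def close_to_printed(value, printed):
    """Agreement within one unit in the 3rd significant figure."""
    scale = 10.0 ** (math.floor(math.log10(abs(printed))) - 2)
    return abs(value - printed) <= scale


class TestUnitMap:
    def test_water_matching_length_scale(self, unit_map):
        # 2 H2O per bead at density 3 -> r_C ~ 5.65 angstrom
        assert close_to_printed(unit_map.length_scale / 1e-10, 5.65)

    def test_time_scale_relation(self, unit_map):
        expected = unit_map.length_scale * math.sqrt(
            unit_map.mass_scale / unit_map.energy_scale)
        assert unit_map.time_scale == pytest.approx(expected, rel=1e-15)

    def test_density_scaling_is_cube_root(self):
        base = build_unit_map(298.15, 997.0, 2, 3)
        dense = build_unit_map(298.15, 8 * 997.0, 2, 3)
        assert dense.length_scale == pytest.approx(base.length_scale / 2,
                                                   rel=1e-12)

    @pytest.mark.parametrize("field,value", [
        ("temperature_kelvin", 0.0), ("water_mass_density", -1.0),
        ("reduced_density", 0.0)])
    def test_nonpositive_inputs_rejected(self, field, value):
        kwargs = dict(temperature_kelvin=298.15, water_mass_density=997.0,
                      water_molecules_per_bead=2, reduced_density=3)
        kwargs[field] = value
        with pytest.raises(ValueError, match=field):
            build_unit_map(**kwargs)


class TestConvert:
    def test_worked_length_conversion(self, unit_map):
        # 7.52 reduced lengths is about 4.25 nm
        nm = convert(7.52, (1, 0, 0, 0), "to_si", unit_map) / 1e-9
        assert close_to_printed(nm, 4.25)

    def test_friction_conversion(self, unit_map):
        si = convert(4.5, (0, 1, 0, -1), "to_si", unit_map)
        assert close_to_printed(si, 1.25e-13)

    def test_zero_maps_to_zero(self, unit_map):
        assert convert(0.0, (2, -1, 1, 3), "to_si", unit_map) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(value=st.one_of(st.just(0.0), st.floats(1e-6, 1e6),
                           st.floats(-1e6, -1e-6)),
           sig=st.tuples(*[st.integers(-3, 3)] * 4))
    def test_round_trip(self, unit_map, value, sig):
        out = convert(convert(value, sig, "to_si", unit_map), sig,
                      "to_reduced", unit_map)
        assert out == pytest.approx(value, rel=1e-12, abs=1e-300)

    def test_bad_signature_rejected(self, unit_map):
        with pytest.raises(ValueError):
            convert(1.0, (1, 0), "to_si", unit_map)
        with pytest.raises(ValueError):
            convert(1.0, (1, 0, 0, 0), "sideways", unit_map)


class TestThermostatAmplitudes:
    def test_published_friction(self):
        assert gamma_from_sigma(3.0, 1.0) == pytest.approx(4.5)

    def test_degenerate_cases(self):
        assert gamma_from_sigma(0.0, 1.0) == 0.0
        assert gamma_from_sigma(2.0, 2.0) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50)
    @given(gamma=st.floats(0.0, 1e6), kT=st.floats(0.01, 100))
    def test_inverse_pair(self, gamma, kT):
        assert gamma_from_sigma(sigma_from_gamma(gamma, kT), kT) == \
            pytest.approx(gamma, rel=1e-12, abs=1e-12)

    def test_nonpositive_kt_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_sigma(3.0, 0.0)


class TestBondRule:
    @settings(derandomize=True, max_examples=30)
    @given(ni=st.integers(1, 8), nj=st.integers(1, 8))
    def test_symmetry(self, ni, nj):
        rule = {"type": "linear_heavy_atoms", "coefficient": 0.1}
        assert bond_length(ni, nj, rule) == bond_length(nj, ni, rule)

    def test_monotone_in_heavy_atoms(self, ff):
        rule = ff.bonded.bond_rule
        values = [bond_length(i, j, rule)
                  for i in range(1, 7) for j in range(i, 7)]
        sums = [i + j for i in range(1, 7) for j in range(i, 7)]
        order = np.argsort(sums)
        assert np.all(np.diff(np.array(values)[order]) >= -1e-12)

    def test_missing_pair_entry_names_pair(self, ff):
        with pytest.raises(KeyError, match="W"):
            ff.bonded.bond_length("C", "W")
        table_rule = {"type": "count_table", "table": {"3-3": 0.6}}
        with pytest.raises(KeyError, match="3-5"):
            bond_length(3, 5, table_rule)


class TestForceFieldLoading:
    def test_default_has_unit_water_cutoff(self, ff):
        assert ff.interactions.rc("W", "W") == 1.0
        assert all(b.mass == 1 for b in ff.beads.values())

    def test_asymmetric_matrix_rejected(self, ff):
        doc = {
            "species": ["W", "X"],
            "beads": {"W": {"molar_mass": 36.0},
                      "X": {"molar_mass": 42.0}},
            "repulsion": [[25.0, 30.0], [31.0, 25.0]],
            "cutoff": [[1.0, 1.0], [1.0, 1.0]],
        }
        with pytest.raises(ForceFieldError, match="asymmetric"):
            load_force_field(doc)

    def test_fluctuation_dissipation_violation_reported(self, ff):
        doc = {
            "species": ["W"],
            "beads": {"W": {"molar_mass": 36.0}},
            "repulsion": [[25.0]],
            "cutoff": [[1.0]],
            "thermostat": {"sigma": 3.0, "gamma": 4.0},
        }
        with pytest.raises(ForceFieldError, match="fluctuation"):
            load_force_field(doc)

    def test_coupling_matches_unit_map(self, ff, unit_map):
        expected = coupling_from_unit_map(unit_map, 78.3)
        assert ff.electrostatics.coupling == pytest.approx(expected)
        # order of magnitude: ~16 for r_C ~ 5.6 angstrom at 25 C
        assert 10 < ff.electrostatics.coupling < 25

    def test_volume_conventions(self):
        half = bead_volume_from_cutoff(1.0, "half_cutoff")
        full = bead_volume_from_cutoff(1.0, "cutoff")
        assert full == pytest.approx(8 * half)
        assert half == pytest.approx(4 / 3 * math.pi / 8)
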