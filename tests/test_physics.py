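"""Attenuation tables, source spectrum, energy bins, unit conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spcct.physics import (
    EnergyBinSet,
    EnergyGrid,
    build_source_spectrum,
    load_attenuation_table,
    mass_attenuation_at,
    mass_to_molar_concentration,
    molar_to_mass_concentration,
)

EDGE_MATERIALS = ("gold", "iodine", "gadolinium")


class TestAttenuationTables:
    def test_water_reference_value(self):
        # NIST tabulates 0.2059 cm²/g for water at 60 keV
        table = load_attenuation_table("water")
        assert mass_attenuation_at(table, 60.0) == pytest.approx(0.2059, rel=1e-3)

    @pytest.mark.parametrize("material", EDGE_MATERIALS)
    def test_kedge_jump_exceeds_factor_two(self, material):
        table = load_attenuation_table(material)
        e = table.kedge_energy
        below = mass_attenuation_at(table, e - 0.1)
        above = mass_attenuation_at(table, e + 0.1)
        assert above / below > 2.0

    @pytest.mark.parametrize("material", EDGE_MATERIALS)
    def test_edge_query_is_right_continuous(self, material):
        table = load_attenuation_table(material)
        e = table.kedge_energy
        at_edge = mass_attenuation_at(table, e)
        assert at_edge == pytest.approx(mass_attenuation_at(table, e + 1e-9), rel=1e-6)
        assert at_edge > 2 * mass_attenuation_at(table, e - 1e-9)

    @pytest.mark.parametrize(
        "material", ("water", "calcium", "gold", "iodine", "gadolinium")
    )
    def test_tabulated_points_reproduced_and_monotone(self, material):
        table = load_attenuation_table(material)
        # interpolation identity at tabulated abscissae (away from the edge)
        for e, v in zip(table.energies, table.mu_over_rho):
            if table.kedge_energy is not None and e == table.kedge_energy:
                continue
            assert mass_attenuation_at(table, float(e)) == pytest.approx(v, rel=1e-12)
        # monotone decreasing between discontinuities
        diffs = np.diff(table.mu_over_rho)
        dup = np.diff(table.energies) == 0
        assert np.all(diffs[~dup] < 0)

    def test_out_of_range_energy_raises(self):
        table = load_attenuation_table("water")
        with pytest.raises(ValueError):
            mass_attenuation_at(table, 5.0)
        with pytest.raises(ValueError):
            mass_attenuation_at(table, 500.0)


class TestSourceSpectrum:
    def test_unfiltered_kramers_shape(self):
        s = build_source_spectrum(120, 0.0)
        e = s.grid.energies
        inside = e < 120
        ratio = s.fluence[inside] / (120.0 - e[inside])
        assert np.allclose(ratio, ratio[0])

    def test_filtration_hardens_beam(self):
        means = [build_source_spectrum(120, t).mean_energy for t in (0.0, 1.0, 2.5)]
        assert means[0] < means[1] < means[2]

    def test_kvp_cutoff(self):
        s = build_source_spectrum(100, 2.5)
        e = s.grid.energies
        assert s.fluence[np.searchsorted(e, 99.0)] > 0
        assert np.all(s.fluence[e > 100.0] == 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_source_spectrum(90)
        with pytest.raises(ValueError):
            build_source_spectrum(120, -1.0)


class TestEnergyBins:
    def test_default_thresholds_partition_detected_band(self):
        bins = EnergyBinSet()
        grid = EnergyGrid.default()
        resp = bins.bin_response(grid.energies)
        e = grid.energies
        total = resp.sum(axis=0)
        assert np.all(total[(e >= 30.0) & (e <= 120.0)] == 1.0)
        assert np.all(total[e < 30.0] == 0.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            EnergyBinSet(thresholds=(30, 30, 78), upper_bound=120)
        with pytest.raises(ValueError):
            EnergyBinSet(thresholds=(30, 53), upper_bound=50)

    def test_energy_grid_invariants(self):
        with pytest.raises(ValueError):
            EnergyGrid(np.linspace(5, 120, 300))
        with pytest.raises(ValueError):
            EnergyGrid(np.linspace(20, 120, 50))


class TestConcentrationConversion:
    @pytest.mark.parametrize(
        "molar,element,expected",
        [
            (40.0, "gold", 7.879),
            (60.0, "iodine", 7.614),
            (0.0, "gold", 0.0),
        ],
    )
    def test_printed_series_values(self, molar, element, expected):
        assert molar_to_mass_concentration(molar, element) == pytest.approx(
            expected, abs=5e-3
        )

    def test_unknown_element(self):
        with pytest.raises(ValueError):
            molar_to_mass_concentration(10.0, "unobtainium")

    @settings(derandomize=True, max_examples=50)
    @given(
        c=st.floats(0.0, 1e3, allow_nan=False),
        element=st.sampled_from(("gold", "iodine", "gadolinium")),
    )
    def test_round_trip_identity(self, c, element):
        back = mass_to_molar_concentration(
            molar_to_mass_concentration(c, element), element
        )
        assert back == pytest.approx(c, rel=1e-12, abs=1e-12)
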