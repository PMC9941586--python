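"""Shell-length allometry, the carbon conversion chain, filter counts,
and foram weighings.

Expected values are frozen from an independent hand/spreadsheet oracle
of the printed conversion chain (WW -> DW x0.28 -> POC x0.25 -> PIC
x(0.27/0.73) -> CaCO3 x8.33).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pelacarb as pc
from pelacarb.biomass import (
    DEFAULT_ALLOMETRY,
    DEFAULT_CHAINS,
    FAMILIES,
    HETEROPOD_CHAIN,
)

#: chain constant mg CaCO3 per mg WW: 0.28 x 0.25 x (0.27/0.73) x 8.33
CHAIN_CONST = 0.28 * 0.25 * (0.27 / 0.73) * 8.33


class TestShellAllometry:
    @pytest.mark.parametrize(
        "family,length,expected",
        [
            # oracle: 0.2152 * 1^2.293 * chain
            ("Cavoliniidae", 1.0, 0.2152 * CHAIN_CONST),
            # oracle: DW = 0.1365 * 2^1.501 = 0.3863480; x0.25 x(27/73) x8.33
            ("Limacinidae", 2.0, 0.29758058211488225),
            # oracle: direct exponential, 0.769 * e^2.3
            ("Atlantidae", 1000.0, 7.6701463077525185),
            # oracle: Carinidae WW chain with heteropod PIC:POC midpoint
            ("Carinidae", 1.5, 0.0888 * 1.5**2.161 * 0.28 * 0.25 * 0.365 * 8.33),
        ],
    )
    def test_frozen_oracle_values(self, family, length, expected):
        got = pc.pteropod_heteropod_caco3(pc.ShellRecord(family, length))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_chain_constant_factorization(self):
        """CaCO3/WW for power_WW families is a single constant, 0.21567."""
        assert pc.CarbonChainParams().caco3_per_ww == pytest.approx(0.21567, abs=5e-6)
        L = 2.37
        got = pc.pteropod_heteropod_caco3(pc.ShellRecord("Cavoliniidae", L))
        assert got == pytest.approx(0.2152 * L**2.293 * CHAIN_CONST, rel=1e-12)

    def test_cymbuliidae_juvenile_clamped_to_zero(self):
        with pytest.warns(UserWarning, match="clamped"):
            got = pc.pteropod_heteropod_caco3(pc.ShellRecord("Cymbuliidae", 0.05))
        assert got == 0.0

    def test_cymbuliidae_linear_chain(self):
        # oracle: DW = 0.0392*2 - 0.003 = 0.0754; x0.25 x(27/73) x8.33
        got = pc.pteropod_heteropod_caco3(pc.ShellRecord("Cymbuliidae", 2.0))
        assert got == pytest.approx(0.0754 * 0.25 * (0.27 / 0.73) * 8.33, rel=1e-12)

    @pytest.mark.parametrize("family", [f for f in FAMILIES if f != "Cymbuliidae"])
    def test_strictly_increasing_in_length(self, family):
        grid = np.linspace(0.05, 50, 200)
        vals = [pc.pteropod_heteropod_caco3(pc.ShellRecord(family, L)) for L in grid]
        assert np.all(np.diff(vals) > 0)

    @given(st.sampled_from(FAMILIES), st.floats(1e-3, 50))
    @settings(max_examples=200, deadline=None)
    def test_finite_nonnegative_over_length_range(self, family, length):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = pc.pteropod_heteropod_caco3(pc.ShellRecord(family, length))
        assert np.isfinite(got) and got >= 0

    def test_rejects_bad_records(self):
        with pytest.raises(ValueError):
            pc.ShellRecord("Cavoliniidae", 0.0)
        with pytest.raises(ValueError):
            pc.ShellRecord("Nautilidae", 1.0)
        with pytest.raises(ValueError):
            pc.ShellRecord("Cavoliniidae", 1.0, count=0)
        with pytest.raises(ValueError):
            pc.pteropod_heteropod_caco3(
                pc.ShellRecord("Cavoliniidae", 1.0), DEFAULT_ALLOMETRY["Limacinidae"]
            )

    def test_chain_validates_molar_ratio(self):
        with pytest.raises(ValueError, match="M\\(CaCO3\\)"):
            pc.CarbonChainParams(caco3_per_pic=8.5)
        assert HETEROPOD_CHAIN.pic_poc_ratio == 0.365

    def test_heteropod_pic_poc_range_midpoint(self):
        assert DEFAULT_CHAINS["Carinidae"].pic_poc_ratio == pytest.approx((0.28 + 0.45) / 2)


class TestFilterCounts:
    def test_concentration_formula(self):
        fc = pc.FilterCount(
            depth=30, effective_filtration_area=1000.0, counted_area=0.35,
            filtered_volume=2.1, coccosphere_counts={"Emiliania huxleyi": 50},
        )
        got = pc.coccolithophore_cell_concentration(fc, "Emiliania huxleyi")
        assert got == pytest.approx(1000 * 50 / (0.35 * 2.1), rel=1e-12)  # 68027.2

    def test_absent_species_counts_zero(self):
        fc = pc.FilterCount(10, 1000.0, 1.0, 3.0)
        assert pc.coccolithophore_cell_concentration(fc, "Coccolithus pelagicus") == 0.0

    def test_identity_when_counted_area_is_filter_area(self):
        fc = pc.FilterCount(10, 5.0, 5.0, 1.0, {"sp": 7})
        assert pc.coccolithophore_cell_concentration(fc, "sp") == pytest.approx(7.0)

    @given(st.integers(0, 500), st.floats(0.35, 3.14), st.floats(2.1, 6.0),
           st.floats(1.1, 4.0))
    @settings(max_examples=100, deadline=None)
    def test_homogeneity(self, count, area, volume, c):
        """Doubling C and V together leaves the concentration unchanged;
        scaling F scales it proportionally."""
        base = pc.FilterCount(10, 1000.0, area, volume, {"sp": count})
        ref = pc.coccolithophore_cell_concentration(base, "sp")
        scaled = pc.FilterCount(10, 1000.0, area, volume * c, {"sp": count * c})
        assert pc.coccolithophore_cell_concentration(scaled, "sp") == pytest.approx(ref)
        bigger = pc.FilterCount(10, 1000.0 * c, area, volume, {"sp": count})
        assert pc.coccolithophore_cell_concentration(bigger, "sp") == pytest.approx(ref * c)

    def test_rejects_degenerate_geometry(self):
        with pytest.raises(ValueError):
            pc.FilterCount(10, 1000.0, 0.0, 2.0)
        with pytest.raises(ValueError):
            pc.FilterCount(10, 1000.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            pc.FilterCount(10, 0.5, 1.0, 2.0)  # F < A


class TestCoccolithMass:
    def test_coccosphere_unit_chain(self):
        table = pc.CoccolithMassTable({"sp": 20}, {"sp": 2.5})
        # 1000 cells/L x 20 liths x 2.5 pg x 1e3 L/m3 x 1e-9 mg/pg
        assert pc.coccolithophore_caco3(1000.0, "sp", table) == pytest.approx(0.05)
        assert pc.coccolithophore_caco3(0.0, "sp", table) == 0.0

    def test_loose_mode_has_no_per_sphere_multiplier(self):
        table = pc.CoccolithMassTable({"sp": 20}, {"sp": 2.5})
        got = pc.coccolithophore_caco3(1e6, "sp", table, mode="loose_coccolith")
        assert got == pytest.approx(2.5)

    def test_missing_species_names_the_species(self):
        table = pc.CoccolithMassTable({"sp": 20}, {"sp": 2.5})
        with pytest.raises(KeyError, match="Gephyrocapsa"):
            pc.coccolithophore_caco3(1.0, "Gephyrocapsa oceanica", table)


class TestForamWeighings:
    def test_split_scaling(self):
        w = pc.ForamWeighing("ge125", 5.0, 40, 0.5)
        assert pc.foraminifera_caco3([w]) == pytest.approx(10.0)

    def test_empty_list_is_zero(self):
        assert pc.foraminifera_caco3([]) == 0.0

    def test_sum_over_size_classes(self):
        ws = [pc.ForamWeighing("lt125", 3.0, 100, 0.25),
              pc.ForamWeighing("ge125", 1.0, 10, 0.25)]
        assert pc.foraminifera_caco3(ws) == pytest.approx(16.0)

    def test_rejects_bad_split_and_inconsistent_weight(self):
        with pytest.raises(ValueError):
            pc.ForamWeighing("ge125", 1.0, 10, 0.0)
        with pytest.raises(ValueError):
            pc.ForamWeighing("ge125", 1.0, 10, 1.5)
        with pytest.raises(ValueError):
            pc.ForamWeighing("ge125", 1.0, 0, 0.5)


def test_atlantidae_length_scale_is_configurable():
    """The heteropod ash-weight fit is near-constant for mm lengths; a
    micron-scale interpretation is available via length_scale."""
    mm = pc.pteropod_heteropod_caco3(pc.ShellRecord("Atlantidae", 1.5))
    assert mm == pytest.approx(0.769 * math.exp(0.0023 * 1.5), rel=1e-12)
    coeffs = pc.AllometricCoeffs("Atlantidae", "exponential_CaCO3", 0.769, 0.0023,
                                 length_scale=1000.0)
    um = pc.pteropod_heteropod_caco3(pc.ShellRecord("Atlantidae", 1.5), coeffs)
    assert um == pytest.approx(0.769 * math.exp(0.0023 * 1500.0), rel=1e-12)
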