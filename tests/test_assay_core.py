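"""Unit handling, Beer-Lambert conversions, percent inhibition and CSV I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import antioxcap as ax
from antioxcap.assay_core import ENDPOINT_COLUMNS, extinction_registry
from antioxcap.exceptions import (
    DegenerateAssayError,
    InvalidParameterError,
    SchemaError,
)


class TestBeerLambert:
    def test_hypochlorite_working_level(self):
        # A=0.0105 at eps=350 over 1 cm is the 30 µmol/L working solution
        coeff = ax.get_extinction("hypochlorite", 292)
        c = ax.absorbance_to_concentration(0.0105, coeff, path_cm=1.0)
        assert c == pytest.approx(3.0e-5, rel=1e-12)

    def test_zero_absorbance(self):
        coeff = ax.get_extinction("crocin")
        assert ax.absorbance_to_concentration(0.0, coeff) == 0.0

    @pytest.mark.parametrize("species", ["crocin", "hypochlorite", "TNB", "H2O2"])
    def test_round_trip_exact_for_registry(self, species):
        coeff = ax.get_extinction(species)
        c = 25e-6  # 25 µmol/L, the crocin working level
        a = ax.concentration_to_absorbance(c, coeff)
        assert ax.absorbance_to_concentration(a, coeff) == pytest.approx(c, rel=1e-15)

    @given(st.floats(min_value=1e-9, max_value=1e-2),
           st.floats(min_value=0.1, max_value=2.0))
    def test_round_trip_property(self, conc, path):
        coeff = ax.get_extinction("crocin")
        a = ax.concentration_to_absorbance(conc, coeff, path)
        back = ax.absorbance_to_concentration(a, coeff, path)
        assert back == pytest.approx(conc, rel=1e-12)

    def test_invalid_path(self):
        coeff = ax.get_extinction("crocin")
        with pytest.raises(InvalidParameterError):
            ax.absorbance_to_concentration(0.1, coeff, path_cm=0.0)

    def test_invalid_epsilon(self):
        with pytest.raises(InvalidParameterError):
            ax.ExtinctionCoefficient("x", 400, -1.0)

    def test_registry_contents(self):
        reg = extinction_registry()
        assert len(reg) == 4
        assert reg[("crocin", 443.0)].epsilon_M_cm == 13726.0
        assert reg[("H2O2", 230.0)].epsilon_M_cm == 80.0


class TestPercentInhibition:
    def test_midpoint_of_abts_window(self):
        # half the 0.750 AU starting absorbance, blank 0 -> 50%
        assert ax.percent_inhibition(0.375, 0.750, 0.0).raw == pytest.approx(50.0)

    def test_limits(self):
        assert ax.percent_inhibition(0.750, 0.750, 0.0).raw == 0.0
        assert ax.percent_inhibition(0.0, 0.750, 0.0).raw == 100.0

    def test_degenerate(self):
        with pytest.raises(DegenerateAssayError):
            ax.percent_inhibition(0.3, 0.5, 0.5)

    def test_negative_raw_preserved_clamped_companion(self):
        inh = ax.percent_inhibition(0.80, 0.750, 0.0)
        assert inh.raw < 0 and inh.clamped == 0.0

    @given(st.floats(min_value=-0.5, max_value=0.5),
           st.floats(min_value=0.0, max_value=0.74),
           st.floats(min_value=0.0, max_value=0.05))
    def test_affine_invariance(self, offset, sample, blank):
        control = 0.750
        base = ax.percent_inhibition(sample, control, blank).raw
        shifted = ax.percent_inhibition(sample + offset, control + offset,
                                        blank + offset).raw
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestMassMolar:
    def test_catalase(self):
        assert ax.mass_to_molar(18.6, 240000) == pytest.approx(77.5, rel=1e-12)

    def test_scale(self):
        assert ax.mass_to_molar(240, 240000) == pytest.approx(1000.0)

    def test_inverse(self):
        assert ax.molar_to_mass(77.5, 240000) == pytest.approx(18.6, rel=1e-12)


def test_reference_concentrations_table():
    """Packaged uremic/physiological table: nine solutes, entry for entry."""
    expected = {
        "L-arginine": (0.230, 0.140),
        "creatinine": (0.880, 0.120),
        "p-cresol": (0.280, 0.021),
        "hippuric acid": (1.700, 0.028),
        "methylguanidine": (0.091, 0.006),
        "phenol": (0.110, 0.015),
        "L-tyrosine": (0.110, 0.027),
        "urea": (33.000, 6.700),
        "uric acid": (0.600, 0.420),
    }
    df = ax.reference_concentrations().set_index("solute")
    assert len(df) == 9
    for solute, (uc, pc) in expected.items():
        assert df.loc[solute, "uremic"] == pytest.approx(uc)
        assert df.loc[solute, "physiological"] == pytest.approx(pc)
    umol = ax.reference_concentrations(units="umol_L").set_index("solute")
    assert umol.loc["uric acid", "uremic"] == pytest.approx(600.0)


def _minimal_plate_df():
    return pd.DataFrame(
        {
            "assay_id": ["ABTS"] * 6,
            "replicate_id": [1] * 6,
            "solute": ["", "", "ua", "ua", "ua", "ua"],
            "conc_umol_L": [0, 0, 5, 10, 20, 40],
            "absorbance": [0.75, 0.0, 0.5, 0.375, 0.25, 0.15],
            "role": ["control", "blank", "sample", "sample", "sample", "sample"],
        }
    )


class TestEndpointCSV:
    def test_minimal_valid_file(self, tmp_path):
        p = tmp_path / "plate.csv"
        _minimal_plate_df().to_csv(p, index=False)
        plate = ax.read_endpoint_csv(p)
        roles = plate.data["role"].value_counts()
        assert roles["control"] == 1 and roles["blank"] == 1 and roles["sample"] == 4

    def test_missing_role_column(self, tmp_path):
        p = tmp_path / "plate.csv"
        _minimal_plate_df().drop(columns=["role"]).to_csv(p, index=False)
        with pytest.raises(SchemaError, match="role"):
            ax.read_endpoint_csv(p)

    def test_non_numeric_absorbance_names_row(self, tmp_path):
        df = _minimal_plate_df().astype({"absorbance": object})
        df.loc[3, "absorbance"] = "oops"
        p = tmp_path / "plate.csv"
        df.to_csv(p, index=False)
        with pytest.raises(SchemaError, match="rows: 4"):
            ax.read_endpoint_csv(p)

    def test_missing_control(self, tmp_path):
        df = _minimal_plate_df()
        df = df[df["role"] != "control"]
        p = tmp_path / "plate.csv"
        df.to_csv(p, index=False)
        with pytest.raises(SchemaError, match="control"):
            ax.read_endpoint_csv(p)

    def test_write_read_round_trip_bit_exact(self, tmp_path):
        cfg = ax.SimulationConfig(seed=7, true_ic50={"uric acid": 16.75})
        plate = ax.simulate_endpoint_assay(cfg)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        ax.write_endpoint_csv(plate, p1)
        back = ax.read_endpoint_csv(p1)
        ax.write_endpoint_csv(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        pd.testing.assert_frame_equal(plate.data[ENDPOINT_COLUMNS],
                                      back.data[ENDPOINT_COLUMNS])


class TestKineticCSV:
    def test_round_trip(self, tmp_path):
        cfg = ax.SimulationConfig(seed=9, true_ic50={})
        traces = ax.simulate_kinetic_panel(cfg, "uric acid", [5.0, 10.0])
        p1, p2 = tmp_path / "k1.csv", tmp_path / "k2.csv"
        ax.write_kinetic_csv(traces, p1)
        back = ax.read_kinetic_csv(p1)
        assert len(back) == len(traces)
        np.testing.assert_array_equal(back[0].time_s, traces[0].time_s)
        ax.write_kinetic_csv(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_column(self, tmp_path):
        p = tmp_path / "k.csv"
        pd.DataFrame({"sample_id": ["a"], "time_s": [0.0]}).to_csv(p, index=False)
        with pytest.raises(SchemaError):
            ax.read_kinetic_csv(p)

    def test_times_must_increase(self):
        with pytest.raises(SchemaError):
            ax.KineticTrace("s", "x", 1.0, 25.0,
                            time_s=[0, 10, 10], abs_443=[0.3, 0.29, 0.28])
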