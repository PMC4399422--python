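"""IC50-proportioned mixture design, dilution accounting and additivity."""

import numpy as np
import pandas as pd
import pytest

import antioxcap as ax
from antioxcap.mixture_design import Interaction
from antioxcap.exceptions import CensoredInputError, InvalidParameterError
from antioxcap.rounding import display_round, round_half_up, truncate

ABTS_IC50 = {"uric acid": 16.75, "phenol": 12.98, "p-cresol": 3.99,
             "L-tyrosine": 5.23}
HOCL_IC50 = {"uric acid": 5.75, "phenol": 8.95, "p-cresol": 15.75,
             "L-tyrosine": 2.83}
CROCIN_IC50 = {"uric acid": 6.90, "phenol": 1125.81, "p-cresol": 1162.31}


class TestDesignStock:
    def test_abts_quaternary_multiplier_2(self):
        spec = ax.design_stock(list(ABTS_IC50.items()), 2.0, 300.0, "ABTS")
        assert dict(spec.stocks) == pytest.approx(
            {"uric acid": 33.5, "phenol": 25.96, "p-cresol": 7.98,
             "L-tyrosine": 10.46})

    def test_hocl_quaternary_multiplier_10(self):
        spec = ax.design_stock(list(HOCL_IC50.items()), 10.0, 1500.0, "HOCL")
        assert dict(spec.stocks) == pytest.approx(
            {"uric acid": 57.5, "phenol": 89.5, "p-cresol": 157.5,
             "L-tyrosine": 28.3})

    def test_single_solute_multiplier_1(self):
        spec = ax.design_stock([("uric acid", 16.75)], 1.0, 300.0)
        assert spec.stocks.iloc[0] == pytest.approx(16.75)

    def test_censored_input_refused(self):
        with pytest.raises(CensoredInputError):
            ax.design_stock([("uric acid", 16.75), ("methylguanidine", None)],
                            2.0, 300.0)

    def test_censored_ic50result_refused(self):
        censored = ax.IC50Result("ABTS", "urea", None, float("nan"),
                                 "FOUR_PARAM_LOGISTIC", True, 330000.0)
        with pytest.raises(CensoredInputError):
            ax.design_stock([censored], 2.0, 300.0)


class TestDilutionAccounting:
    def test_abts_worked_volume(self):
        spec = ax.design_stock(list(ABTS_IC50.items()), 2.0, 300.0, "ABTS")
        conc = ax.component_concentration(spec, 39.85)
        assert conc["uric acid"] == pytest.approx(4.4499, abs=1e-4)
        assert round_half_up(conc["uric acid"]) == 4.45

    def test_hocl_worked_volume(self):
        spec = ax.design_stock(list(HOCL_IC50.items()), 10.0, 1500.0, "HOCL")
        conc = ax.component_concentration(spec, 41.70)
        assert conc["uric acid"] == pytest.approx(1.5985, abs=1e-4)
        assert round_half_up(conc["uric acid"]) == 1.60

    def test_zero_volume(self):
        spec = ax.design_stock(list(ABTS_IC50.items()), 2.0, 300.0)
        assert (ax.component_concentration(spec, 0.0) == 0).all()

    def test_volume_out_of_range(self):
        spec = ax.design_stock(list(ABTS_IC50.items()), 2.0, 300.0)
        with pytest.raises(InvalidParameterError):
            ax.component_concentration(spec, 301.0)


class TestIC50Fraction:
    def test_equal_across_components_and_value(self):
        spec = ax.design_stock(list(ABTS_IC50.items()), 2.0, 300.0, "ABTS")
        fracs = ax.ic50_fraction(spec, 39.85)
        assert fracs.nunique() == 1
        assert fracs.iloc[0] == pytest.approx(2.0 * 39.85 / 300.0, rel=1e-12)  # 0.2657
        assert truncate(fracs.iloc[0]) == 0.26

    def test_additive_prediction_volume(self):
        # V = Vf/(n*multiplier) puts the Loewe sum at 1: fraction 1/n each
        spec = ax.design_stock(list(ABTS_IC50.items()), 2.0, 300.0)
        v = 300.0 / (4 * 2.0)
        fracs = ax.ic50_fraction(spec, v)
        assert np.allclose(fracs, 0.25)
        assert ax.mixture_design.loewe_sum(spec, v) == pytest.approx(1.0)

    def test_zero_volume(self):
        spec = ax.design_stock(list(ABTS_IC50.items()), 2.0, 300.0)
        assert (ax.ic50_fraction(spec, 0.0) == 0).all()


class TestProjection:
    def test_binary_projections(self):
        assert ax.projected_ic50([6.90, 1125.81]) == pytest.approx(566.355)
        assert truncate(ax.projected_ic50([6.90, 1125.81])) == 566.35
        assert truncate(ax.projected_ic50([6.90, 1162.31])) == 584.60
        assert ax.projected_ic50([1125.81, 1162.31]) == pytest.approx(1144.06)

    def test_identical_components(self):
        assert ax.projected_ic50([7.0, 7.0, 7.0, 7.0]) == 7.0


class TestAdditivityIndex:
    def test_subadditive_binary_crocin_values(self):
        idx, cls = ax.additivity_index(851.22, 566.35)
        assert idx == pytest.approx(1.503, abs=0.001)
        assert cls is Interaction.SUB_ADDITIVE
        idx2, cls2 = ax.additivity_index(739.52, 584.60)
        assert idx2 == pytest.approx(1.265, abs=0.001)
        assert cls2 is Interaction.SUB_ADDITIVE

    def test_additive_and_synergy_bands(self):
        assert ax.additivity_index(566.35, 566.35)[1] is Interaction.ADDITIVE
        assert ax.additivity_index(100.0, 200.0)[1] is Interaction.SUPRA_ADDITIVE

    def test_tau_configurable(self):
        assert ax.additivity_index(1.08, 1.0, tau=0.05)[1] is Interaction.SUB_ADDITIVE
        assert ax.additivity_index(1.08, 1.0, tau=0.10)[1] is Interaction.ADDITIVE


class TestCaptureShares:
    @pytest.mark.parametrize("n, share", [(4, 12.5), (2, 25.0), (1, 50.0)])
    def test_equal_shares(self, n, share):
        ic50s = list(ABTS_IC50.items())[:n]
        spec = ax.design_stock(ic50s, 2.0, 300.0)
        shares = ax.additive_capture_shares(spec)
        assert np.allclose(shares, share)

    def test_measured_shares_at_additive_ic50(self):
        spec = ax.design_stock(list(ABTS_IC50.items()), 2.0, 300.0)
        v50 = 300.0 / (4 * 2.0)
        assert np.allclose(ax.capture_shares_at_volume(spec, v50), 12.5)


class TestMixtureReport:
    def _binary_crocin_curve(self, lam):
        spec = ax.design_stock(list(CROCIN_IC50.items())[:2], 10.0, 2000.0, "CROCIN")
        cfg = ax.SimulationConfig(
            seed=5, assay_id="CROCIN", noise_sd=0.0,
            mixture=ax.MixtureBlock(spec=spec, lam=lam, n_replicates=2),
        )
        plate = ax.simulate_mixture_response(cfg)
        return spec, ax.build_inhibition_curve(plate, "+".join(spec.solutes))

    def test_binary_crocin_worked_example(self):
        # lam = 1.503 puts the mixture IC50 at 150.3 µL of stock
        spec, curve = self._binary_crocin_curve(lam=1.503)
        rep = ax.mixture_report(spec, curve)
        assert rep.ic50_volume_uL == pytest.approx(150.3, rel=1e-4)
        assert rep.component_conc_at_ic50["uric acid"] == pytest.approx(5.18, abs=0.01)
        assert rep.component_conc_at_ic50["phenol"] == pytest.approx(846.04, abs=0.01)
        df = rep.to_frame(convention="truncate")
        assert df.attrs["observed_total_umol_L"] == 851.22
        assert df.attrs["projected_total_umol_L"] == 566.35
        assert rep.classification is Interaction.SUB_ADDITIVE

    def test_exactly_additive_mixture(self):
        spec, curve = self._binary_crocin_curve(lam=1.0)
        rep = ax.mixture_report(spec, curve)
        assert rep.additivity_index == pytest.approx(1.0, abs=1e-4)
        assert rep.classification is Interaction.ADDITIVE

    def test_quaternary_observed_total_is_component_sum(self):
        spec = ax.design_stock(list(ABTS_IC50.items()), 2.0, 300.0, "ABTS")
        cfg = ax.SimulationConfig(seed=6, noise_sd=0.0,
                                  mixture=ax.MixtureBlock(spec=spec, lam=1.0))
        plate = ax.simulate_mixture_response(cfg)
        rep = ax.mixture_report(spec, ax.build_inhibition_curve(plate, plate.solutes[0]))
        assert rep.observed_total_umol_L == pytest.approx(
            rep.component_conc_at_ic50.sum(), rel=1e-12)

    def test_censored_mixture_curve(self):
        pts = pd.DataFrame({"conc": [10.0, 50.0, 250.0],
                            "inhibition": [2.0, 8.0, 20.0], "replicate_id": 1})
        curve = ax.InhibitionCurve("CROCIN", "mix", pts, dose_label="volume_uL")
        spec = ax.design_stock(list(CROCIN_IC50.items())[:2], 10.0, 2000.0)
        rep = ax.mixture_report(spec, curve)
        assert rep.censored and rep.ic50_volume_uL is None


class TestPrintedTotalsIdentity:
    @pytest.mark.parametrize(
        "cells, total",
        [((5.18, 846.04), 851.22), ((4.36, 735.16), 739.52),
         ((858.43, 886.26), 1744.69)],
    )
    def test_sum_of_displayed_cells(self, cells, total):
        assert round(sum(cells), 2) == total


class TestRounding:
    def test_both_conventions(self):
        assert round_half_up(4.4499) == 4.45
        assert truncate(4.4499) == 4.44
        assert round_half_up(1.5985) == 1.60
        assert truncate(0.2657) == 0.26
        assert truncate(566.355) == 566.35
        assert display_round(2.5, "half-up", 0) == 3.0

    def test_unknown_convention(self):
        with pytest.raises(ValueError):
            display_round(1.0, "banker")
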