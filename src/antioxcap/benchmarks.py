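"""Published in-vitro potency benchmarks for uremic solutes and Trolox.

These reference values — IC50s per assay (µmol/L), competitive-kinetic
slopes (ka/kc) for the crocin bleaching assay, and the stock-mixture worked
examples — serve as ground truth for the synthetic-data generator and as
cross-checks in the test suite. ``None`` marks a censored result: no 50%
inhibition was reached at the highest concentration tested, which for those
panels was 10x the mean uremic plasma level.
"""

from __future__ import annotations

from .assay_core import reference_concentrations

#: Per-assay IC50 values (µmol/L); None = censored (no effect at c_max).
REFERENCE_IC50: dict[str, dict[str, float | None]] = {
    "ABTS": {
        "L-arginine": 61350.00,
        "creatinine": 536.26,
        "p-cresol": 3.99,
        "hippuric acid": None,
        "methylguanidine": None,
        "phenol": 12.98,
        "Trolox": 16.45,
        "L-tyrosine": 5.23,
        "urea": None,
        "uric acid": 16.75,
    },
    "HOCL": {
        "L-arginine": 92100.00,
        "creatinine": 9130.00,
        "p-cresol": 15.75,
        "hippuric acid": 1600.00,
        "methylguanidine": None,
        "phenol": 8.95,
        "Trolox": 8.65,
        "L-tyrosine": 2.83,
        "urea": 5600.00,
        "uric acid": 5.75,
    },
    "SUPEROXIDE": {
        "L-arginine": None,
        "creatinine": None,
        "p-cresol": None,
        "hippuric acid": None,
        "methylguanidine": None,
        "phenol": None,
        "Trolox": 2223.10,
        "L-tyrosine": None,
        "urea": None,
        "uric acid": None,
    },
    # No uremic solute (nor Trolox) captures H2O2; catalase validates the assay.
    "H2O2": {
        "L-arginine": None,
        "creatinine": None,
        "p-cresol": None,
        "hippuric acid": None,
        "methylguanidine": None,
        "phenol": None,
        "Trolox": None,
        "L-tyrosine": None,
        "urea": None,
        "uric acid": None,
    },
    "CROCIN": {
        "uric acid": 6.90,
        "Trolox": 10.09,
        "phenol": 1125.81,
        "p-cresol": 1162.31,
        "L-tyrosine": None,
        "methylguanidine": None,
        "L-arginine": None,
        "hippuric acid": None,
        "creatinine": None,
        "urea": None,
    },
}

#: Crocin-bleaching competition slopes ka/kc (dimensionless), decreasing efficacy.
CROCIN_SLOPES: dict[str, float] = {
    "uric acid": 4.015,
    "Trolox": 2.230,
    "phenol": 0.023,
    "p-cresol": 0.016,
    "L-tyrosine": 0.007,
    "methylguanidine": 9.272e-4,
    "L-arginine": 7.727e-4,
    "hippuric acid": 8.000e-5,
    "creatinine": 6.776e-5,
    "urea": 2.558e-6,
}

#: Catalase benchmark for the H2O2 assay: IC50 as activity, mass and molar dose.
CATALASE = {"ic50_units_mL": 0.55, "ic50_ug_mL": 18.6, "mw_Da": 240000.0,
            "ic50_nmol_L": 77.5}

#: Crocin working concentration (µmol/L) in the peroxyl-radical assay.
CROCIN_CONC_UMOL_L = 25.0

#: Starting absorbance of the ABTS radical solution at 734 nm.
ABTS_CONTROL_ABS = 0.750


def censoring_cmax(solute: str) -> float:
    """Highest concentration tested for no-effect solutes: 10x uremic level (µmol/L)."""
    ref = reference_concentrations(units="umol_L").set_index("solute")
    return float(10.0 * ref.loc[solute, "uremic"])
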