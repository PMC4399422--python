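"""Core domain types and primitive calculations for ROS-scavenging assays.

This module holds everything the higher analysis layers share:

* :class:`ExtinctionCoefficient` and a packaged registry of molar
  absorptivities (crocin, hypochlorite, TNB, H2O2) for Beer-Lambert
  conversions between absorbance and molar concentration;
* :class:`EndpointPlate` — a tidy table of endpoint absorbance readings
  (control / blank / sample wells) for the decolorization-style assays
  (ABTS radical cation at 734 nm, HOCl/TMB at 655 nm, superoxide/NBT at
  560 nm, H2O2/TNB at 412 nm);
* :class:`KineticTrace` — a time series of crocin absorbance at 443 nm for
  the competitive peroxyl-radical (crocin bleaching) assay;
* :class:`ReferenceConcentrations` loaders for the packaged table of uremic
  and physiological plasma concentrations of the nine classic uremic solutes;
* the percent-inhibition primitive and mass/molar unit conversions;
* readers and writers for the package's two CSV dialects.

Units follow the conventions used throughout the package: concentrations in
µmol/L in the analysis layers (the reference table is stored in mmol/L, as
plasma concentrations are conventionally reported, and converted on load),
volumes in µL, absorbance in AU, time in seconds, molar absorptivity in
M⁻¹·cm⁻¹ and optical path in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateAssayError,
    InvalidParameterError,
    SchemaError,
    SoluteNotFoundError,
)

__all__ = [
    "ASSAY_IDS",
    "ExtinctionCoefficient",
    "EndpointPlate",
    "KineticTrace",
    "Inhibition",
    "extinction_registry",
    "get_extinction",
    "reference_concentrations",
    "absorbance_to_concentration",
    "concentration_to_absorbance",
    "percent_inhibition",
    "mass_to_molar",
    "molar_to_mass",
    "read_endpoint_csv",
    "write_endpoint_csv",
    "read_kinetic_csv",
    "write_kinetic_csv",
]

#: Endpoint assay identifiers understood by the package. CROCIN is kinetic
#: and handled by :mod:`antioxcap.competition_kinetics`, but mixture response
#: curves measured in that assay also flow through EndpointPlate containers.
ASSAY_IDS = ("ABTS", "HOCL", "SUPEROXIDE", "H2O2", "CROCIN")

ENDPOINT_COLUMNS = ["assay_id", "replicate_id", "solute", "conc_umol_L", "absorbance", "role"]
KINETIC_COLUMNS = ["sample_id", "solute", "conc_umol_L", "crocin_umol_L", "time_s", "abs_443"]
ROLES = ("control", "blank", "sample")


# ---------------------------------------------------------------------------
# Extinction coefficients and Beer-Lambert conversions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtinctionCoefficient:
    """Molar absorptivity of a species at a given wavelength.

    Parameters
    ----------
    species : str
        Label of the absorbing species (e.g. ``"crocin"``).
    wavelength_nm : float
        Wavelength of the measurement, nm.
    epsilon_M_cm : float
        Molar absorptivity, M⁻¹·cm⁻¹. Must be positive.
    solvent : str
        Solvent in which epsilon was determined.
    path_length_default_cm : float
        Default optical path used when a conversion does not specify one.
        Microplate geometries vary and the effective path is configurable
        everywhere; 1 cm is the conventional cuvette default.
    """

    species: str
    wavelength_nm: float
    epsilon_M_cm: float
    solvent: str = ""
    path_length_default_cm: float = 1.0

    def __post_init__(self):
        if self.epsilon_M_cm <= 0:
            raise InvalidParameterError(f"epsilon must be > 0, got {self.epsilon_M_cm}")
        if self.wavelength_nm <= 0:
            raise InvalidParameterError(f"wavelength must be > 0, got {self.wavelength_nm}")
        if self.path_length_default_cm <= 0:
            raise InvalidParameterError("default path length must be > 0")


def _load_packaged_csv(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("antioxcap").joinpath("data", name)) as p:
        return pd.read_csv(p)


_REGISTRY: dict[tuple[str, float], ExtinctionCoefficient] | None = None


def extinction_registry() -> dict[tuple[str, float], ExtinctionCoefficient]:
    """Packaged registry of extinction coefficients, keyed by (species, wavelength)."""
    global _REGISTRY
    if _REGISTRY is None:
        df = _load_packaged_csv("extinction_coefficients.csv")
        _REGISTRY = {
            (r.species, float(r.wavelength_nm)): ExtinctionCoefficient(
                species=r.species,
                wavelength_nm=float(r.wavelength_nm),
                epsilon_M_cm=float(r.epsilon_M_cm),
                solvent=r.solvent,
            )
            for r in df.itertuples()
        }
    return _REGISTRY


def get_extinction(species: str, wavelength_nm: float | None = None) -> ExtinctionCoefficient:
    """Look up a packaged extinction coefficient.

    ``wavelength_nm`` may be omitted when the species has a single entry.
    """
    reg = extinction_registry()
    hits = [
        c for (sp, wl), c in reg.items()
        if sp == species and (wavelength_nm is None or wl == float(wavelength_nm))
    ]
    if not hits:
        raise SoluteNotFoundError(f"no extinction coefficient for {species!r} @ {wavelength_nm}")
    if len(hits) > 1:
        raise InvalidParameterError(
            f"ambiguous lookup for {species!r}: specify the wavelength"
        )
    return hits[0]


def absorbance_to_concentration(
    absorbance: float,
    coeff: ExtinctionCoefficient,
    path_cm: float | None = None,
) -> float:
    """Convert absorbance to molar concentration via Beer-Lambert (mol/L).

    ``c = A / (epsilon * l)`` with epsilon in M⁻¹·cm⁻¹ and l in cm.
    """
    if path_cm is None:
        path_cm = coeff.path_length_default_cm
    if path_cm <= 0:
        raise InvalidParameterError(f"path length must be > 0, got {path_cm}")
    if absorbance < 0:
        raise InvalidParameterError(f"absorbance must be >= 0, got {absorbance}")
    return absorbance / (coeff.epsilon_M_cm * path_cm)


def concentration_to_absorbance(
    concentration_M: float,
    coeff: ExtinctionCoefficient,
    path_cm: float | None = None,
) -> float:
    """Inverse of :func:`absorbance_to_concentration`; exact round-trip."""
    if path_cm is None:
        path_cm = coeff.path_length_default_cm
    if path_cm <= 0:
        raise InvalidParameterError(f"path length must be > 0, got {path_cm}")
    if concentration_M < 0:
        raise InvalidParameterError("concentration must be >= 0")
    return concentration_M * coeff.epsilon_M_cm * path_cm


# ---------------------------------------------------------------------------
# Percent inhibition and unit conversions
# ---------------------------------------------------------------------------

class Inhibition(NamedTuple):
    """Percent inhibition: raw value plus the [0, 100]-clamped companion.

    Negative raw values (apparent pro-oxidant behaviour, usually noise) are
    preserved in ``raw``; fitting layers use ``clamped``.
    """

    raw: float
    clamped: float


def percent_inhibition(sample: float, control: float, blank: float = 0.0) -> Inhibition:
    """Percent inhibition of an endpoint signal.

    The control well carries the full (100%) reaction and the blank carries
    none, so ``100 * (control - sample) / (control - blank)``. Adding any
    constant offset to all three readings leaves the result unchanged, which
    is what makes a shared reading-blank subtraction a no-op here.
    """
    denom = control - blank
    if denom == 0:
        raise DegenerateAssayError("control equals blank: assay window is empty")
    raw = 100.0 * (control - sample) / denom
    return Inhibition(raw=raw, clamped=float(min(100.0, max(0.0, raw))))


def mass_to_molar(mass_ug_mL: float, molecular_weight_Da: float) -> float:
    """Convert a mass concentration (µg/mL) to nmol/L given the molecular weight.

    µg/mL equals mg/L, so nmol/L = mass / MW * 1e6. The classic check is
    catalase: 18.6 µg/mL at MW 240,000 Da is 77.5 nmol/L.
    """
    if mass_ug_mL <= 0 or molecular_weight_Da <= 0:
        raise InvalidParameterError("mass concentration and MW must be > 0")
    return mass_ug_mL / molecular_weight_Da * 1e6


def molar_to_mass(conc_nmol_L: float, molecular_weight_Da: float) -> float:
    """Inverse of :func:`mass_to_molar`: nmol/L -> µg/mL."""
    if conc_nmol_L <= 0 or molecular_weight_Da <= 0:
        raise InvalidParameterError("concentration and MW must be > 0")
    return conc_nmol_L * molecular_weight_Da / 1e6


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class EndpointPlate:
    """Tidy endpoint-absorbance table for one assay.

    ``data`` columns: ``assay_id, replicate_id, solute, conc_umol_L,
    absorbance, role`` with role in {control, blank, sample}. For mixture
    response curves the dose column carries the added stock volume in µL
    instead of a concentration; ``dose_kind`` records which.
    """

    data: pd.DataFrame
    wavelength_nm: float | None = None
    dose_kind: str = "concentration"  # or "volume"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        self.validate()

    @property
    def assay_id(self) -> str:
        return str(self.data["assay_id"].iloc[0])

    @property
    def solutes(self) -> list[str]:
        return sorted(self.data.loc[self.data["role"] == "sample", "solute"].unique())

    @property
    def replicates(self) -> list[int]:
        return sorted(self.data["replicate_id"].unique())

    def validate(self) -> None:
        df = self.data
        missing = [c for c in ENDPOINT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"endpoint table missing columns: {missing}")
        bad_role = df.index[~df["role"].isin(ROLES)].tolist()
        if bad_role:
            raise SchemaError("invalid role (must be control/blank/sample)",
                              rows=[i + 1 for i in bad_role])
        if not np.issubdtype(df["absorbance"].dtype, np.number):
            raise SchemaError("absorbance column is not numeric")
        neg = df.index[df["conc_umol_L"] < 0].tolist()
        if neg:
            raise SchemaError("negative dose", rows=[i + 1 for i in neg])
        zero_sample = df.index[(df["role"] == "sample") & (df["conc_umol_L"] <= 0)].tolist()
        if zero_sample:
            raise SchemaError("sample rows must have dose > 0",
                              rows=[i + 1 for i in zero_sample])
        for (assay, rep), grp in df.groupby(["assay_id", "replicate_id"]):
            roles = set(grp["role"])
            if "control" not in roles or "blank" not in roles:
                raise SchemaError(
                    f"assay {assay} replicate {rep} lacks a control and/or blank row"
                )

    def control_blank(self, replicate_id: int) -> tuple[float, float]:
        """Mean control and blank absorbance for one replicate."""
        grp = self.data[self.data["replicate_id"] == replicate_id]
        if grp.empty:
            raise SoluteNotFoundError(f"replicate {replicate_id} not on plate")
        control = float(grp.loc[grp["role"] == "control", "absorbance"].mean())
        blank = float(grp.loc[grp["role"] == "blank", "absorbance"].mean())
        return control, blank


@dataclass
class KineticTrace:
    """One crocin-bleaching time course (absorbance at 443 nm vs time).

    ``conc_umol_L`` is the antioxidant (sample) concentration [A] and
    ``crocin_umol_L`` the crocin concentration [C]; both nominal initial
    values. Times must be strictly increasing.
    """

    sample_id: str
    solute: str
    conc_umol_L: float
    crocin_umol_L: float
    time_s: np.ndarray
    abs_443: np.ndarray
    blank_corrected: bool = False

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.abs_443 = np.asarray(self.abs_443, dtype=float)
        if self.time_s.shape != self.abs_443.shape:
            raise SchemaError("time and absorbance arrays differ in length")
        if np.any(np.diff(self.time_s) <= 0):
            raise SchemaError(f"trace {self.sample_id}: times not strictly increasing")
        if self.crocin_umol_L <= 0:
            raise InvalidParameterError("crocin concentration must be > 0")
        if self.conc_umol_L < 0:
            raise InvalidParameterError("antioxidant concentration must be >= 0")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


def reference_concentrations(units: str = "mmol_L") -> pd.DataFrame:
    """Packaged uremic vs physiological plasma concentrations of nine solutes.

    Stored in mmol/L (the convention for plasma levels); pass
    ``units="umol_L"`` to get the µmol/L working units of the analysis layers.
    Columns: ``solute, uremic, physiological``.
    """
    df = _load_packaged_csv("reference_concentrations.csv").rename(
        columns={"uremic_mmol_L": "uremic", "physiological_mmol_L": "physiological"}
    )
    if units == "umol_L":
        df[["uremic", "physiological"]] *= 1000.0
    elif units != "mmol_L":
        raise InvalidParameterError(f"unknown units {units!r}")
    return df


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _coerce_numeric(df: pd.DataFrame, cols: Iterable[str], path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad or coerced.isna().any():
            bad_all = sorted(set(bad) | set(df.index[coerced.isna()].tolist()))
            raise SchemaError(f"{path}: non-numeric value(s) in column {col!r}",
                              rows=[i + 1 for i in bad_all])
        df[col] = coerced
    return df


def read_endpoint_csv(path) -> EndpointPlate:
    """Read an endpoint plate from the package's CSV dialect.

    Columns (exact names): ``assay_id,replicate_id,solute,conc_umol_L,
    absorbance,role``. Violations raise :class:`SchemaError` naming the
    offending rows (1-based, excluding the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"assay_id": str, "solute": str, "role": str},
                         float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as one error class
        raise SchemaError(f"{path}: unreadable CSV ({exc})") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    _check_columns(df, ENDPOINT_COLUMNS, path)
    df["solute"] = df["solute"].fillna("")  # control/blank rows have no solute
    df = _coerce_numeric(df, ["replicate_id", "conc_umol_L", "absorbance"], path)
    df["replicate_id"] = df["replicate_id"].astype(int)
    return EndpointPlate(data=df[ENDPOINT_COLUMNS])


def write_endpoint_csv(plate: EndpointPlate, path) -> None:
    plate.data[ENDPOINT_COLUMNS].to_csv(path, index=False)


def read_kinetic_csv(path) -> list[KineticTrace]:
    """Read kinetic traces (one row per time point) from the kinetic dialect.

    Columns: ``sample_id,solute,conc_umol_L,crocin_umol_L,time_s,abs_443``.
    Rows are grouped by ``sample_id``; each group becomes one
    :class:`KineticTrace`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "solute": str},
                         float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        raise SchemaError(f"{path}: unreadable CSV ({exc})") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    _check_columns(df, KINETIC_COLUMNS, path)
    df = _coerce_numeric(df, ["conc_umol_L", "crocin_umol_L", "time_s", "abs_443"], path)
    traces = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_s")
        traces.append(
            KineticTrace(
                sample_id=str(sample_id),
                solute=str(grp["solute"].iloc[0]),
                conc_umol_L=float(grp["conc_umol_L"].iloc[0]),
                crocin_umol_L=float(grp["crocin_umol_L"].iloc[0]),
                time_s=grp["time_s"].to_numpy(),
                abs_443=grp["abs_443"].to_numpy(),
            )
        )
    return traces


def write_kinetic_csv(traces: list[KineticTrace], path) -> None:
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": t.sample_id,
                    "solute": t.solute,
                    "conc_umol_L": t.conc_umol_L,
                    "crocin_umol_L": t.crocin_umol_L,
                    "time_s": t.time_s,
                    "abs_443": t.abs_443,
                }
            )
        )
    pd.concat(frames, ignore_index=True)[KINETIC_COLUMNS].to_csv(path, index=False)
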