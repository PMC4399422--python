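"""Publication-style report tables (TSV) and machine twins (JSON).

Layouts mirror the conventional presentation of scavenging panels: a
solute x assay potency table with censored cells rendered ``ND>c_max``, a
competition table (solute, slope, IC50-or-censored) with slopes below 1e-3
in scientific notation, and mixture tables with per-component dilution
accounting plus the additivity index. Every emitted file embeds the
rounding convention and a config hash so a re-run with the same inputs is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .competition_kinetics import CompetitionFit
from .dose_response import IC50Result
from .mixture_design import MixtureReport
from .rounding import display_round

__all__ = [
    "config_hash",
    "write_table",
    "potency_table",
    "competition_table",
    "mixture_table",
    "results_to_json",
]


def config_hash(config: dict) -> str:
    """Short sha256 of a canonical-JSON rendering of the run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _header(convention: str, cfg_hash: str) -> str:
    return (f"# antioxcap {__version__}\n"
            f"# rounding_convention={convention}\n"
            f"# config_sha256={cfg_hash}\n")


def write_table(df: pd.DataFrame, path, convention: str, config: dict) -> None:
    """Write a TSV with the metadata header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(convention, config_hash(config)))
        df.to_csv(fh, sep="\t", index=False)


def _fmt_value(value: float, convention: str) -> str:
    if value < 1e-3:
        return f"{value:.3e}"
    return f"{display_round(value, convention):.2f}"


def potency_table(results: list[IC50Result], convention: str = "half-up") -> pd.DataFrame:
    """Solute x assay IC50 table; censored cells rendered ``ND>c_max``."""
    rows = []
    for r in results:
        rows.append(
            {
                "solute": r.solute,
                "assay_id": r.assay_id,
                "ic50_umol_L": f"ND>{r.c_max_tested:g}" if r.censored
                else _fmt_value(r.value, convention),
                "sem_umol_L": "" if (r.censored or not np.isfinite(r.sem))
                else _fmt_value(r.sem, convention),
                "method": r.method,
                "n_replicates": r.n_replicates,
            }
        )
    long = pd.DataFrame(rows)
    wide = long.pivot_table(index="solute", columns="assay_id", values="ic50_umol_L",
                            aggfunc="first").reset_index()
    wide.columns.name = None
    return wide if wide.shape[1] > 2 else long


def competition_table(fits: list[CompetitionFit],
                      ic50s: list[IC50Result] | None = None,
                      convention: str = "half-up") -> pd.DataFrame:
    """Competition summary: solute, ka/kc slope, Trolox equivalents, IC50."""
    by_solute = {r.solute: r for r in (ic50s or [])}
    rows = []
    for f in sorted(fits, key=lambda f: -f.slope):
        slope = f"{f.slope:.3e}" if abs(f.slope) < 1e-3 else f"{f.slope:.3f}"
        r = by_solute.get(f.solute)
        if r is None:
            ic50 = ""
        elif r.censored:
            ic50 = f"ND>{r.c_max_tested:g}"
        else:
            ic50 = _fmt_value(r.value, convention)
        rows.append(
            {
                "solute": f.solute,
                "slope_ka_kc": slope,
                "intercept": f"{f.intercept:.3f}",
                "r_squared": f"{f.r_squared:.4f}",
                "trolox_equivalents": ""
                if f.trolox_equivalents is None else f"{f.trolox_equivalents:.4g}",
                "ic50_umol_L": ic50,
            }
        )
    return pd.DataFrame(rows)


def mixture_table(report: MixtureReport, convention: str = "half-up") -> pd.DataFrame:
    """Per-component mixture table with the summary attrs flattened in."""
    df = report.to_frame(convention)
    if not report.censored:
        extra = pd.DataFrame(
            [{"solute": "TOTAL",
              "conc_at_ic50_umol_L": df.attrs["observed_total_umol_L"]},
             {"solute": "PROJECTED",
              "conc_at_ic50_umol_L": df.attrs["projected_total_umol_L"]},
             {"solute": f"INDEX ({df.attrs['classification']})",
              "conc_at_ic50_umol_L": df.attrs["additivity_index"]}]
        )
        df = pd.concat([df, extra], ignore_index=True)
    return df


def results_to_json(results: list[IC50Result], path, config: dict,
                    convention: str = "half-up") -> None:
    payload = {
        "tool": f"antioxcap {__version__}",
        "rounding_convention": convention,
        "config_sha256": config_hash(config),
        "results": [
            {
                "solute": r.solute,
                "assay_id": r.assay_id,
                "censored": r.censored,
                "ic50_umol_L": None if r.censored else r.value,
                "bound_umol_L": r.c_max_tested if r.censored else None,
                "sem_umol_L": None if (r.censored or not np.isfinite(r.sem)) else r.sem,
                "method": r.method,
                "hill": r.hill,
                "n_replicates": r.n_replicates,
            }
            for r in results
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
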