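"""Competitive kinetics of the crocin bleaching (peroxyl-radical) assay.

Peroxyl radicals, generated at a constant rate by AAPH thermolysis, bleach
crocin (followed at 443 nm). An antioxidant A competes with crocin C for the
radicals, lowering the bleaching rate from v0 to::

    v = v0 * kc[C] / (kc[C] + ka[A])        <=>        v0/v = 1 + (ka/kc) [A]/[C]

so the slope of v0/v against [A]/[C] estimates the rate-constant ratio
ka/kc — the relative radical-capture capacity. Dividing a sample's slope by
the slope of Trolox expresses it in Trolox equivalents. The same traces also
yield percent inhibition, %In = (1 - v/v0) * 100, from which an IC50 can be
fit exactly as for the endpoint assays; on data that follow the competition
model exactly, IC50 = [C] / (ka/kc).

Rates are extracted as least-squares slopes of the absorbance trace over a
window where bleaching is linear (default 60-600 s: linear after about one
minute, monitored for ten). Rate ratios are taken in AU/s (the extinction
coefficient cancels); molar rates via the crocin epsilon are available for
reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assay_core import KineticTrace, get_extinction
from .dose_response import DoseResponseModel, IC50Result, InhibitionCurve
from .exceptions import (
    DegenerateAssayError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "DEFAULT_RATE_WINDOW",
    "BleachingRate",
    "CompetitionFit",
    "CompetitionModel",
    "extract_rate",
    "velocity_ratio",
    "fit_competition_slope",
    "trolox_equivalents",
    "percent_inhibition_kinetic",
    "ic50_from_kinetics",
]

DEFAULT_RATE_WINDOW = (60.0, 600.0)


@dataclass
class BleachingRate:
    """Bleaching rate of one trace: |slope| of A443 vs time over a window."""

    sample_id: str
    v_au_s: float
    window_s: tuple[float, float]
    r_squared: float
    non_bleaching: bool = False

    @property
    def v_molar_s(self) -> float:
        """Rate as crocin consumption, (mol/L)/s, via the crocin epsilon."""
        eps = get_extinction("crocin", 443)
        return self.v_au_s / (eps.epsilon_M_cm * eps.path_length_default_cm)


def extract_rate(trace: KineticTrace, window_s: tuple[float, float] = DEFAULT_RATE_WINDOW,
                 path_cm: float = 1.0) -> BleachingRate:
    """Least-squares bleaching rate over ``window_s``, sign-flipped positive.

    A non-negative fitted slope (constant or rising absorbance) means no
    bleaching: the rate is reported as 0 and flagged. Adding a constant to
    every absorbance leaves the result unchanged.
    """
    t0, t1 = window_s
    if not (trace.time_s[0] <= t0 and t1 <= trace.time_s[-1]):
        raise InvalidParameterError(
            f"window {window_s} not contained in trace span "
            f"({trace.time_s[0]}, {trace.time_s[-1]})"
        )
    mask = (trace.time_s >= t0) & (trace.time_s <= t1)
    if int(mask.sum()) < 5:
        raise InsufficientDataError(
            f"need >= 5 points in the rate window, got {int(mask.sum())}"
        )
    t = trace.time_s[mask]
    a = trace.abs_443[mask]
    if np.ptp(a) == 0.0:  # constant trace: slope 0, r^2 undefined -> 0
        return BleachingRate(trace.sample_id, 0.0, (t0, t1), 0.0, non_bleaching=True)
    res = stats.linregress(t, a)
    slope = float(res.slope)
    r2 = float(res.rvalue**2)
    if slope >= 0:
        return BleachingRate(trace.sample_id, 0.0, (t0, t1), r2, non_bleaching=True)
    return BleachingRate(trace.sample_id, -slope, (t0, t1), r2)


def velocity_ratio(v0: "BleachingRate | float", v: "BleachingRate | float") -> float:
    """v0/v. Complete inhibition (v = 0) returns the ``inf`` sentinel."""
    v0_val = v0.v_au_s if isinstance(v0, BleachingRate) else float(v0)
    v_val = v.v_au_s if isinstance(v, BleachingRate) else float(v)
    if v0_val <= 0:
        raise DegenerateAssayError("uninhibited rate v0 must be > 0")
    if v_val == 0:
        return math.inf
    return v0_val / v_val


def percent_inhibition_kinetic(v0: "BleachingRate | float", v: "BleachingRate | float") -> float:
    """%In = (1 - v/v0) * 100 — inhibition of the bleaching rate."""
    v0_val = v0.v_au_s if isinstance(v0, BleachingRate) else float(v0)
    v_val = v.v_au_s if isinstance(v, BleachingRate) else float(v)
    if v0_val <= 0:
        raise DegenerateAssayError("uninhibited rate v0 must be > 0")
    return 100.0 * (1.0 - v_val / v0_val)


@dataclass
class CompetitionFit:
    """OLS fit of v0/v on [A]/[C]: slope = ka/kc.

    Under the competition model the intercept is 1; ``intercept_warning``
    flags |intercept - 1| > 0.2 as model inadequacy.
    """

    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    points: pd.DataFrame
    solute: str = ""
    intercept_warning: bool = False
    trolox_equivalents: float | None = None

    def summary(self) -> str:
        lines = [
            "Competition-kinetics fit (v0/v ~ [A]/[C])",
            "=" * 46,
            f"solute:          {self.solute or 'n/a'}",
            f"n points:        {len(self.points)}",
            f"slope (ka/kc):   {self.slope:.6g} +/- {self.slope_stderr:.3g}",
            f"intercept:       {self.intercept:.4f}"
            + ("   ** deviates from 1 **" if self.intercept_warning else ""),
            f"R-squared:       {self.r_squared:.4f}",
        ]
        if self.trolox_equivalents is not None:
            lines.append(f"Trolox equiv.:   {self.trolox_equivalents:.4g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.points["ratio_AC"]
        ax.plot(x, self.points["v0_over_v"], "o", label="observed")
        grid = np.linspace(0, float(x.max()) * 1.05, 50)
        ax.plot(grid, self.intercept + self.slope * grid, "-",
                label=f"slope = {self.slope:.3g}")
        ax.set_xlabel("[A]/[C]")
        ax.set_ylabel("v0 / v")
        ax.set_title(self.solute or "competition fit")
        ax.legend()
        return ax


class CompetitionModel:
    """Linear competition model for one antioxidant's (v0/v, [A]/[C]) points.

    Accepts a DataFrame with columns ``ratio_AC`` and ``v0_over_v`` (or a
    sequence of pairs). Infinite ratios (complete inhibition) are excluded
    with a warning before fitting. ``fit()`` returns a :class:`CompetitionFit`.
    """

    def __init__(self, points, solute: str = ""):
        if isinstance(points, pd.DataFrame):
            df = points[["ratio_AC", "v0_over_v"]].copy()
        else:
            df = pd.DataFrame(points, columns=["ratio_AC", "v0_over_v"])
        finite = np.isfinite(df["v0_over_v"])
        if (~finite).any():
            warnings.warn(
                f"excluding {int((~finite).sum())} complete-inhibition point(s)",
                stacklevel=2,
            )
            df = df[finite]
        self.points = df.reset_index(drop=True)
        self.solute = solute
        x = self.points["ratio_AC"].to_numpy(float)
        if len(np.unique(x)) < 3:
            raise InsufficientDataError("need >= 3 distinct [A]/[C] values")
        pos = x[x > 0]
        if np.ptp(x) == 0 or pos.size == 0:
            raise InsufficientDataError("degenerate [A]/[C] range")
        if x.min() > 0 and x.max() / x.min() < 4.0:
            warnings.warn("[A]/[C] spans < 4-fold: slope may be poorly determined",
                          stacklevel=2)

    @classmethod
    def from_traces(cls, v0_trace: KineticTrace, traces: list[KineticTrace],
                    window_s: tuple[float, float] = DEFAULT_RATE_WINDOW,
                    solute: str = "") -> "CompetitionModel":
        """Build from a no-antioxidant reference trace and sample traces."""
        v0 = extract_rate(v0_trace, window_s)
        rows = [(0.0, 1.0)] if v0_trace.conc_umol_L == 0 else []
        for tr in traces:
            v = extract_rate(tr, window_s)
            rows.append((tr.conc_umol_L / tr.crocin_umol_L, velocity_ratio(v0, v)))
        return cls(rows, solute=solute or (traces[0].solute if traces else ""))

    def fit(self) -> CompetitionFit:
        x = self.points["ratio_AC"].to_numpy(float)
        y = self.points["v0_over_v"].to_numpy(float)
        res = stats.linregress(x, y)
        r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 1.0
        intercept = float(res.intercept)
        warn = abs(intercept - 1.0) > 0.2
        if warn:
            warnings.warn(
                f"competition-fit intercept {intercept:.3f} deviates from 1: "
                "the linear competition model may not hold", stacklevel=2,
            )
        return CompetitionFit(
            slope=float(res.slope),
            intercept=intercept,
            r_squared=r2,
            slope_stderr=float(res.stderr) if res.stderr is not None else float("nan"),
            points=self.points,
            solute=self.solute,
            intercept_warning=warn,
        )


def fit_competition_slope(points, solute: str = "") -> CompetitionFit:
    """Functional wrapper around :class:`CompetitionModel`."""
    return CompetitionModel(points, solute=solute).fit()


def trolox_equivalents(sample_fit: CompetitionFit, trolox_fit: CompetitionFit) -> float:
    """Relative capacity = sample slope / Trolox slope."""
    if trolox_fit.slope <= 0:
        raise DegenerateAssayError("Trolox slope must be > 0")
    return sample_fit.slope / trolox_fit.slope


def ic50_from_kinetics(series, assay_id: str = "CROCIN", solute: str = "",
                       method: str = "auto") -> IC50Result:
    """IC50 from a (concentration, %In) series of kinetic inhibition values.

    ``series`` is a DataFrame with columns ``conc`` and ``inhibition``
    (optionally ``replicate_id``; the crocin assay runs in duplicate) or a
    sequence of (conc, %In) pairs. Contracts are those of the endpoint IC50
    fit, including censoring when %In never reaches 50.
    """
    if isinstance(series, pd.DataFrame):
        df = series.copy()
    else:
        df = pd.DataFrame(series, columns=["conc", "inhibition"])
    if "replicate_id" not in df.columns:
        df["replicate_id"] = 1
    curve = InhibitionCurve(assay_id=assay_id, solute=solute, points=df)
    return DoseResponseModel(curve).fit(method=method).ic50_result()
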