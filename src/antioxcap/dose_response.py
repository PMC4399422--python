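"""Inhibition curves and IC50 estimation.

The central object is :class:`DoseResponseModel`, built from an
:class:`InhibitionCurve` (or a tidy DataFrame); ``fit()`` returns a
:class:`DoseResponseResults` carrying the IC50, its SEM across replicates,
fit diagnostics and a ``summary()`` table, in the style of statsmodels.

Model
-----
The primary estimator is a four-parameter-logistic-style curve with the
floor fixed at 0% and the ceiling at 100%::

    inhibition(c) = 100 * c**h / (c**h + IC50**h),   h >= 0.2 free

fit by least squares on the [0, 100]-clamped inhibition values. When the
optimizer fails, or when data are non-sigmoidal, the estimator falls back to
monotone (isotonic-smoothed) linear interpolation of the lowest 50%
crossing. The method actually used is always recorded.

A curve whose maximum mean inhibition stays below 50% at every tested
concentration is *censored*: the IC50 is reported as ``> c_max`` and no
numeric value is returned, mirroring the "no effect at the concentration
used" convention of scavenging panels.

The point estimate is the mean of per-replicate fits (assays run in
triplicate, crocin in duplicate) and the SEM is the standard error across
those replicate-level estimates; the pooled-data fit is kept as a
diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .assay_core import EndpointPlate, percent_inhibition
from .exceptions import InsufficientDataError, SoluteNotFoundError

__all__ = [
    "InhibitionCurve",
    "IC50Result",
    "DoseResponseModel",
    "DoseResponseResults",
    "build_inhibition_curve",
    "fit_ic50",
    "ic50_sem",
    "FOUR_PARAM_LOGISTIC",
    "MONOTONE_INTERPOLATION",
]

FOUR_PARAM_LOGISTIC = "FOUR_PARAM_LOGISTIC"
MONOTONE_INTERPOLATION = "MONOTONE_INTERPOLATION"


@dataclass
class InhibitionCurve:
    """Per-assay, per-solute inhibition measurements with replicate structure.

    ``points`` columns: ``conc`` (µmol/L, or µL for mixture volume curves),
    ``inhibition`` (percent, raw — may be negative or exceed 100 under
    noise) and ``replicate_id``.
    """

    assay_id: str
    solute: str
    points: pd.DataFrame
    dose_label: str = "conc_umol_L"

    def __post_init__(self):
        required = {"conc", "inhibition", "replicate_id"}
        missing = required - set(self.points.columns)
        if missing:
            raise InsufficientDataError(f"curve points missing columns {sorted(missing)}")
        if not np.all(np.isfinite(self.points["inhibition"])):
            raise InsufficientDataError("non-finite inhibition values")
        self.points = self.points.reset_index(drop=True)

    @property
    def n_replicates(self) -> int:
        return int(self.points["replicate_id"].nunique())

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.points["conc"].unique())

    @property
    def c_max(self) -> float:
        return float(self.points["conc"].max())

    def mean_by_conc(self) -> pd.DataFrame:
        return (
            self.points.groupby("conc", as_index=False)["inhibition"]
            .mean()
            .sort_values("conc", ignore_index=True)
        )


@dataclass
class IC50Result:
    """Potency estimate for one (assay, solute) pair.

    ``value`` is the IC50 in µmol/L (or µL for volume curves); ``None`` when
    censored, in which case the estimate is the bound ``> c_max_tested``.
    """

    assay_id: str
    solute: str
    value: float | None
    sem: float
    method: str
    censored: bool
    c_max_tested: float
    hill: float | None = None
    n_replicates: int = 0
    replicate_values: list[float] = field(default_factory=list)

    @property
    def display(self) -> str:
        if self.censored:
            return f"> {self.c_max_tested:g}"
        return f"{self.value:.2f}"

    def __post_init__(self):
        if not self.censored and (self.value is None or self.value <= 0):
            raise InsufficientDataError("uncensored IC50 must be positive")


def build_inhibition_curve(plate: EndpointPlate, solute: str) -> InhibitionCurve:
    """Compose percent inhibition over a plate into one solute's curve.

    Each sample well is referenced to the control/blank of its own
    replicate, so replicate-level drift in the control signal cancels.
    """
    rows = plate.data[(plate.data["role"] == "sample") & (plate.data["solute"] == solute)]
    if rows.empty:
        raise SoluteNotFoundError(f"solute {solute!r} not on plate {plate.assay_id}")
    records = []
    for rep, grp in rows.groupby("replicate_id"):
        control, blank = plate.control_blank(int(rep))
        for _, r in grp.iterrows():
            inh = percent_inhibition(r["absorbance"], control, blank)
            records.append((float(r["conc_umol_L"]), inh.raw, int(rep)))
    points = pd.DataFrame(records, columns=["conc", "inhibition", "replicate_id"])
    dose_label = "volume_uL" if plate.dose_kind == "volume" else "conc_umol_L"
    return InhibitionCurve(assay_id=plate.assay_id, solute=solute, points=points,
                           dose_label=dose_label)


def _hill(c, ic50, h):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ch = np.power(c, h)
        return 100.0 * ch / (ch + ic50**h)


def _interp_crossing(conc: np.ndarray, inh: np.ndarray) -> float | None:
    """Lowest 50% crossing of the isotonic-smoothed mean curve (linear interp)."""
    order = np.argsort(conc)
    c, y = conc[order], inh[order]
    y = optimize.isotonic_regression(y, increasing=True).x
    if y[0] >= 50.0:  # already above 50 at the lowest dose: cannot bracket
        return float(c[0])
    above = np.nonzero(y >= 50.0)[0]
    if above.size == 0:
        return None
    j = above[0]
    i = j - 1
    if y[j] == y[i]:  # flat isotonic block touching 50 exactly
        return float(c[j])
    return float(c[i] + (50.0 - y[i]) * (c[j] - c[i]) / (y[j] - y[i]))


def _fit_logistic(conc: np.ndarray, inh: np.ndarray) -> tuple[float, float]:
    """Least-squares (IC50, h) for the 0/100-anchored logistic; raises on failure."""
    clamped = np.clip(inh, 0.0, 100.0)
    guess = _interp_crossing(conc, clamped)
    pos = conc[conc > 0]
    k0 = guess if guess and guess > 0 else float(np.exp(np.mean(np.log(pos))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = optimize.curve_fit(
            _hill, conc, clamped,
            p0=[k0, 1.0],
            bounds=([1e-12, 0.2], [np.inf, 10.0]),
            maxfev=10000,
        )
    ic50, h = float(popt[0]), float(popt[1])
    if not np.isfinite(ic50) or ic50 <= 0:
        raise RuntimeError("logistic fit diverged")
    # reject fits far outside the tested range: treat as non-sigmoidal data
    if ic50 < pos.min() / 1e3 or ic50 > pos.max() * 1e3:
        raise RuntimeError("logistic fit outside plausible range")
    return ic50, h


def _fit_single(conc: np.ndarray, inh: np.ndarray, method: str):
    """One dataset -> (ic50, hill, method_used). May return None if no crossing."""
    if method in ("auto", "logistic"):
        try:
            ic50, h = _fit_logistic(conc, inh)
            return ic50, h, FOUR_PARAM_LOGISTIC
        except Exception:
            if method == "logistic":
                raise
    ic50 = _interp_crossing(conc, np.clip(inh, 0.0, 100.0))
    if ic50 is None:
        return None
    return ic50, None, MONOTONE_INTERPOLATION


class DoseResponseModel:
    """Dose-response (IC50) model for one inhibition curve.

    Parameters
    ----------
    curve : InhibitionCurve
        The observed (conc, inhibition, replicate) points.

    Examples
    --------
    >>> model = DoseResponseModel(curve)
    >>> res = model.fit()
    >>> res.ic50, res.sem, res.method
    """

    def __init__(self, curve: InhibitionCurve):
        self.curve = curve
        if len(curve.concentrations) < 3:
            raise InsufficientDataError(
                f"need >= 3 distinct concentrations, got {len(curve.concentrations)}"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, assay_id: str = "", solute: str = "",
                       dose_label: str = "conc_umol_L") -> "DoseResponseModel":
        """Build from a tidy frame with conc/inhibition[/replicate_id] columns."""
        df = df.copy()
        if "replicate_id" not in df.columns:
            df["replicate_id"] = 1
        return cls(InhibitionCurve(assay_id=assay_id, solute=solute, points=df,
                                   dose_label=dose_label))

    @classmethod
    def from_plate(cls, plate: EndpointPlate, solute: str) -> "DoseResponseModel":
        return cls(build_inhibition_curve(plate, solute))

    def fit(self, method: str = "auto") -> "DoseResponseResults":
        """Estimate the IC50.

        ``method``: ``"auto"`` (logistic with interpolation fallback),
        ``"logistic"`` or ``"interpolation"``.
        """
        curve = self.curve
        conc = curve.points["conc"].to_numpy(dtype=float)
        inh = curve.points["inhibition"].to_numpy(dtype=float)
        means = curve.mean_by_conc()

        # Censoring decided on pooled per-concentration means.
        if means["inhibition"].max() < 50.0:
            return DoseResponseResults(
                model=self, ic50=None, hill=None, sem=float("nan"),
                method=MONOTONE_INTERPOLATION if method == "interpolation"
                else FOUR_PARAM_LOGISTIC,
                censored=True, replicate_ic50s=[], pooled_ic50=None,
            )

        meth = "interpolation" if method == "interpolation" else method
        pooled = _fit_single(conc, inh, meth)
        if pooled is None:
            raise InsufficientDataError("no 50% crossing despite uncensored means")
        pooled_ic50, pooled_h, method_used = pooled

        rep_vals: list[float] = []
        for _, grp in curve.points.groupby("replicate_id"):
            if grp["conc"].nunique() < 3:
                continue
            try:
                one = _fit_single(grp["conc"].to_numpy(float),
                                  grp["inhibition"].to_numpy(float), meth)
            except Exception:
                one = None
            if one is not None:
                rep_vals.append(one[0])

        if len(rep_vals) >= 2:
            value = float(np.mean(rep_vals))
            sem = float(stats.sem(rep_vals))
        elif len(rep_vals) == 1:
            value, sem = rep_vals[0], float("nan")
        else:
            value, sem = pooled_ic50, float("nan")

        return DoseResponseResults(
            model=self, ic50=value, hill=pooled_h, sem=sem, method=method_used,
            censored=False, replicate_ic50s=rep_vals, pooled_ic50=pooled_ic50,
        )


@dataclass
class DoseResponseResults:
    """Fit results for a :class:`DoseResponseModel`."""

    model: DoseResponseModel
    ic50: float | None
    hill: float | None
    sem: float
    method: str
    censored: bool
    replicate_ic50s: list[float]
    pooled_ic50: float | None

    @property
    def curve(self) -> InhibitionCurve:
        return self.model.curve

    @property
    def c_max_tested(self) -> float:
        return self.curve.c_max

    def predict(self, conc) -> np.ndarray:
        if self.censored or self.ic50 is None:
            raise InsufficientDataError("censored result has no fitted curve")
        h = self.hill if self.hill is not None else 1.0
        return _hill(np.asarray(conc, float), self.ic50, h)

    @property
    def rsquared(self) -> float:
        if self.censored:
            return float("nan")
        y = np.clip(self.curve.points["inhibition"].to_numpy(float), 0, 100)
        yhat = self.predict(self.curve.points["conc"].to_numpy(float))
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    def ic50_result(self) -> IC50Result:
        return IC50Result(
            assay_id=self.curve.assay_id,
            solute=self.curve.solute,
            value=self.ic50,
            sem=self.sem,
            method=self.method,
            censored=self.censored,
            c_max_tested=self.c_max_tested,
            hill=self.hill,
            n_replicates=self.curve.n_replicates,
            replicate_values=list(self.replicate_ic50s),
        )

    def summary(self) -> str:
        c = self.curve
        lines = [
            "Dose-response fit",
            "=" * 46,
            f"assay:        {c.assay_id}",
            f"solute:       {c.solute}",
            f"n points:     {len(c.points)}  ({c.n_replicates} replicates)",
            f"dose axis:    {c.dose_label}",
            f"method:       {self.method}",
        ]
        if self.censored:
            lines.append(f"IC50:         > {self.c_max_tested:g} (censored)")
        else:
            sem = f"{self.sem:.4g}" if np.isfinite(self.sem) else "n/a"
            hill = f"{self.hill:.3f}" if self.hill is not None else "n/a"
            lines += [
                f"IC50:         {self.ic50:.6g} +/- {sem} (SEM, "
                f"{len(self.replicate_ic50s)} replicate fits)",
                f"Hill slope:   {hill}",
                f"pooled IC50:  {self.pooled_ic50:.6g}",
                f"R-squared:    {self.rsquared:.4f}",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot: points, fitted curve and the IC50 marker."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.curve.points
        ax.semilogx(pts["conc"], pts["inhibition"], "o", alpha=0.6, label="observed")
        if not self.censored:
            grid = np.geomspace(pts["conc"][pts["conc"] > 0].min(), pts["conc"].max(), 200)
            ax.semilogx(grid, self.predict(grid), "-", label="fit")
            ax.axvline(self.ic50, ls="--", color="grey")
            ax.axhline(50, ls=":", color="grey")
        ax.set_xlabel(self.curve.dose_label)
        ax.set_ylabel("inhibition (%)")
        ax.set_title(f"{self.curve.assay_id}: {self.curve.solute}")
        ax.legend()
        return ax


def fit_ic50(curve: InhibitionCurve, method: str = "auto") -> IC50Result:
    """Functional wrapper: fit a curve and return the :class:`IC50Result`."""
    return DoseResponseModel(curve).fit(method=method).ic50_result()


def ic50_sem(replicate_ic50s) -> tuple[float, float]:
    """Mean and SEM over replicate-level IC50 estimates.

    With fewer than two estimates the SEM is undefined and returned as NaN
    (with a warning), matching the flagged-undefined contract.
    """
    vals = np.asarray(list(replicate_ic50s), dtype=float)
    if vals.size == 0:
        raise InsufficientDataError("no replicate estimates")
    if vals.size < 2:
        warnings.warn("SEM undefined for a single replicate estimate", stacklevel=2)
        return float(vals[0]), float("nan")
    return float(vals.mean()), float(stats.sem(vals))
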