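"""IC50-proportioned mixtures: design, dilution accounting and additivity.

The IC50 is used here as an analytical tool: a stock mixture is prepared
with every component at the *same multiple* of its individual IC50
(``stock_i = multiplier * IC50_i``). Adding a volume V of that stock to a
final assay volume Vf then holds every component at the identical fraction
of its IC50::

    f_i = c_i / IC50_i = multiplier * V / Vf        (equal for all i)

Under Loewe additivity (components acting as dilutions of one another,
shared unit Hill slope) the mixture reaches 50% inhibition exactly when the
Loewe sum S = sum_i c_i/IC50_i equals 1, i.e. each of n components sits at
1/n of its own IC50 and contributes 50/n percentage points of the 50%
capture (12.5% for quaternary, 25% for binary mixtures). The additive
projection of the mixture IC50 as a total concentration is then the plain
mean of the individual IC50s. The additivity index — observed total at the
mixture IC50 over that projection — classifies the interaction: ~1
additive, >1 sub-additive (antagonism), <1 supra-additive (synergy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .dose_response import DoseResponseModel, IC50Result, InhibitionCurve
from .exceptions import CensoredInputError, InvalidParameterError
from .rounding import display_round

__all__ = [
    "MixtureComponent",
    "MixtureSpec",
    "MixtureReport",
    "Interaction",
    "design_stock",
    "component_concentration",
    "ic50_fraction",
    "projected_ic50",
    "additivity_index",
    "additive_capture_shares",
    "capture_shares_at_volume",
    "loewe_sum",
    "mixture_report",
]


class Interaction(str, Enum):
    ADDITIVE = "ADDITIVE"
    SUB_ADDITIVE = "SUB_ADDITIVE"
    SUPRA_ADDITIVE = "SUPRA_ADDITIVE"


@dataclass(frozen=True)
class MixtureComponent:
    solute: str
    individual_ic50_umol_L: float
    stock_conc_umol_L: float


@dataclass
class MixtureSpec:
    """An IC50-proportioned stock mixture design.

    Invariant (by construction in :func:`design_stock`):
    ``stock_conc_i = multiplier * individual_ic50_i`` exactly, with one
    shared multiplier.
    """

    components: list[MixtureComponent]
    multiplier: float
    final_volume_uL: float
    assay_id: str = ""

    def __post_init__(self):
        if self.multiplier <= 0:
            raise InvalidParameterError("multiplier must be > 0")
        if self.final_volume_uL <= 0:
            raise InvalidParameterError("final volume must be > 0")
        if not self.components:
            raise InvalidParameterError("mixture needs >= 1 component")
        for comp in self.components:
            if comp.individual_ic50_umol_L <= 0:
                raise InvalidParameterError(f"{comp.solute}: IC50 must be > 0")
            if not np.isclose(comp.stock_conc_umol_L,
                              self.multiplier * comp.individual_ic50_umol_L,
                              rtol=0, atol=1e-9 * max(1.0, comp.stock_conc_umol_L)):
                raise InvalidParameterError(
                    f"{comp.solute}: stock {comp.stock_conc_umol_L} != "
                    f"multiplier x IC50 = {self.multiplier * comp.individual_ic50_umol_L}"
                )

    @property
    def n(self) -> int:
        return len(self.components)

    @property
    def solutes(self) -> list[str]:
        return [c.solute for c in self.components]

    @property
    def ic50s(self) -> pd.Series:
        return pd.Series({c.solute: c.individual_ic50_umol_L for c in self.components})

    @property
    def stocks(self) -> pd.Series:
        return pd.Series({c.solute: c.stock_conc_umol_L for c in self.components})


def design_stock(ic50s, multiplier: float, final_volume_uL: float,
                 assay_id: str = "") -> MixtureSpec:
    """Design an IC50-proportioned stock: ``stock_i = multiplier * IC50_i``.

    ``ic50s``: mapping/sequence of (solute, IC50 µmol/L) or
    :class:`~antioxcap.dose_response.IC50Result` objects. Any censored input
    is refused — a no-effect bound cannot anchor a proportioned design.
    """
    pairs: list[tuple[str, float]] = []
    items = ic50s.items() if isinstance(ic50s, dict) else ic50s
    for item in items:
        if isinstance(item, IC50Result):
            if item.censored:
                raise CensoredInputError(
                    f"{item.solute}: IC50 is censored ({item.display}); an "
                    "IC50-proportioned mixture needs a finite potency"
                )
            pairs.append((item.solute, float(item.value)))
        else:
            solute, value = item
            if value is None or (isinstance(value, float) and not np.isfinite(value)):
                raise CensoredInputError(f"{solute}: censored/undefined IC50")
            pairs.append((str(solute), float(value)))
    comps = [
        MixtureComponent(solute, ic50, multiplier * ic50) for solute, ic50 in pairs
    ]
    return MixtureSpec(components=comps, multiplier=multiplier,
                       final_volume_uL=final_volume_uL, assay_id=assay_id)


def component_concentration(spec: MixtureSpec, added_volume_uL: float) -> pd.Series:
    """Per-component concentration (µmol/L) after adding stock volume V:
    ``c_i = stock_i * V / Vf``."""
    if not 0 <= added_volume_uL <= spec.final_volume_uL:
        raise InvalidParameterError(
            f"volume {added_volume_uL} outside [0, {spec.final_volume_uL}] µL"
        )
    return spec.stocks * (added_volume_uL / spec.final_volume_uL)


def ic50_fraction(spec: MixtureSpec, added_volume_uL: float) -> pd.Series:
    """Each component's concentration as a fraction of its own IC50.

    By construction this equals ``multiplier * V / Vf`` for every component;
    the identity is asserted to machine precision.
    """
    fracs = component_concentration(spec, added_volume_uL) / spec.ic50s
    expected = spec.multiplier * added_volume_uL / spec.final_volume_uL
    assert np.allclose(fracs.to_numpy(), expected, rtol=1e-12, atol=1e-12), \
        "IC50 fractions diverged across components of a proportioned spec"
    return fracs


def loewe_sum(spec: MixtureSpec, added_volume_uL: float) -> float:
    """Loewe sum S = sum_i c_i / IC50_i at the given added volume."""
    return float(ic50_fraction(spec, added_volume_uL).sum())


def projected_ic50(ic50s) -> float:
    """Additive projection of the mixture IC50 (total µmol/L): mean of the
    individual IC50s, valid for IC50-proportioned mixtures of any n >= 2."""
    vals = np.asarray(list(ic50s), dtype=float)
    if vals.size < 2:
        raise InvalidParameterError("projection needs >= 2 components")
    if np.any(vals <= 0):
        raise InvalidParameterError("all IC50s must be > 0")
    return float(vals.mean())


def additivity_index(observed_total: float, projected_total: float,
                     tau: float = 0.10) -> tuple[float, Interaction]:
    """Observed/projected mixture IC50 ratio with interaction class.

    ``tau`` is the half-width of the ADDITIVE band around 1.
    """
    if observed_total <= 0 or projected_total <= 0:
        raise InvalidParameterError("totals must be > 0")
    index = observed_total / projected_total
    if index > 1.0 + tau:
        cls = Interaction.SUB_ADDITIVE
    elif index < 1.0 - tau:
        cls = Interaction.SUPRA_ADDITIVE
    else:
        cls = Interaction.ADDITIVE
    return index, cls


def additive_capture_shares(spec: MixtureSpec) -> pd.Series:
    """Capture shares (percentage points of the 50% effect) under exact
    additivity at the mixture IC50: 50/n for each of n components."""
    share = 50.0 / spec.n
    return pd.Series({c.solute: share for c in spec.components})


def capture_shares_at_volume(spec: MixtureSpec, added_volume_uL: float) -> pd.Series:
    """Measured capture shares under the additive response at a given volume.

    Component i captures ``100 * S_i / (1 + S)`` percentage points, where
    S_i = c_i/IC50_i and S is the Loewe sum; at the additive mixture IC50
    (S = 1) this is 50/n each.
    """
    fracs = ic50_fraction(spec, added_volume_uL)
    total = float(fracs.sum())
    return 100.0 * fracs / (1.0 + total)


@dataclass
class MixtureReport:
    """Observed-vs-additive analysis of one mixture response curve."""

    spec: MixtureSpec
    censored: bool
    ic50_volume_uL: float | None
    ic50_volume_sem_uL: float
    component_conc_at_ic50: pd.Series | None
    ratio_to_individual_ic50: pd.Series | None
    observed_total_umol_L: float | None
    projected_total_umol_L: float
    additivity_index: float | None
    classification: Interaction | None
    tau: float
    c_max_volume_uL: float | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self, convention: str = "half-up") -> pd.DataFrame:
        """Per-component table (2-dp display); total = sum of displayed cells.

        The displayed total is the sum of the *rounded* component
        concentrations so that the printed column is internally consistent.
        """
        if self.censored:
            rows = [
                {"solute": c.solute, "ic50_volume_uL": f"ND>{self.c_max_volume_uL:g}",
                 "conc_at_ic50_umol_L": "", "individual_ic50_umol_L":
                 display_round(c.individual_ic50_umol_L, convention),
                 "ratio_to_ic50": ""}
                for c in self.spec.components
            ]
            return pd.DataFrame(rows)
        rows = []
        disp_concs = {
            s: display_round(v, convention)
            for s, v in self.component_conc_at_ic50.items()
        }
        for c in self.spec.components:
            rows.append(
                {
                    "solute": c.solute,
                    "ic50_volume_uL": display_round(self.ic50_volume_uL, convention),
                    "conc_at_ic50_umol_L": disp_concs[c.solute],
                    "individual_ic50_umol_L": display_round(c.individual_ic50_umol_L,
                                                            convention),
                    "ratio_to_ic50": display_round(
                        self.ratio_to_individual_ic50[c.solute], convention),
                }
            )
        df = pd.DataFrame(rows)
        # sum the displayed (2-dp) cells exactly, free of float representation
        from decimal import Decimal

        df.attrs["observed_total_umol_L"] = float(
            sum(Decimal(f"{v:.2f}") for v in disp_concs.values()))
        df.attrs["projected_total_umol_L"] = display_round(
            self.projected_total_umol_L, convention)
        df.attrs["additivity_index"] = display_round(self.additivity_index, convention,
                                                     ndigits=3)
        df.attrs["classification"] = self.classification.value
        df.attrs["rounding_convention"] = convention
        return df

    def summary(self, convention: str = "half-up") -> str:
        if self.censored:
            return (f"Mixture ({', '.join(self.spec.solutes)}): censored — no 50% "
                    f"inhibition up to {self.c_max_volume_uL:g} µL of stock")
        df = self.to_frame(convention)
        lines = [
            f"Mixture report ({self.spec.assay_id or 'assay'}; "
            f"{self.spec.n} components, multiplier {self.spec.multiplier:g}, "
            f"final volume {self.spec.final_volume_uL:g} µL)",
            "=" * 60,
            df.to_string(index=False),
            f"observed total at IC50:  {df.attrs['observed_total_umol_L']} µmol/L",
            f"additive projection:     {df.attrs['projected_total_umol_L']} µmol/L",
            f"additivity index:        {df.attrs['additivity_index']} "
            f"({self.classification.value}, tau={self.tau})",
        ]
        return "\n".join(lines)


def mixture_report(spec: MixtureSpec, mixture_curve: InhibitionCurve,
                   tau: float = 0.10, method: str = "auto") -> MixtureReport:
    """Fit the mixture IC50 (volume axis, µL) and assemble the full report.

    ``mixture_curve`` must carry added stock volume on its dose axis. A
    censored curve yields a censored report.
    """
    res = DoseResponseModel(mixture_curve).fit(method=method)
    projected = projected_ic50(spec.ic50s) if spec.n >= 2 else float(spec.ic50s.iloc[0])
    if res.censored:
        return MixtureReport(
            spec=spec, censored=True, ic50_volume_uL=None,
            ic50_volume_sem_uL=float("nan"), component_conc_at_ic50=None,
            ratio_to_individual_ic50=None, observed_total_umol_L=None,
            projected_total_umol_L=projected, additivity_index=None,
            classification=None, tau=tau, c_max_volume_uL=res.c_max_tested,
        )
    v50 = float(res.ic50)
    concs = component_concentration(spec, v50)
    ratios = ic50_fraction(spec, v50)
    observed_total = float(concs.sum())
    index, cls = additivity_index(observed_total, projected, tau=tau)
    return MixtureReport(
        spec=spec, censored=False, ic50_volume_uL=v50,
        ic50_volume_sem_uL=float(res.sem), component_conc_at_ic50=concs,
        ratio_to_individual_ic50=ratios, observed_total_umol_L=observed_total,
        projected_total_umol_L=projected, additivity_index=index,
        classification=cls, tau=tau,
    )
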