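"""Synthetic assay-data generator.

Emulates the statistical structure the analysis layers assume, so the whole
pipeline is testable end to end without instrument data:

* endpoint plates — hyperbolic/Hill scavenging response around a true IC50,
  triplicate wells, Gaussian absorbance noise on every well (control and
  blank included), censored "no effect" solutes;
* crocin kinetic traces — constant-rate peroxyl-radical generation (AAPH
  thermolysis), competition between crocin and antioxidant with the exact
  rate law v = R_g * kc[C]/(kc[C] + ka[A]), a lag before the linear
  bleaching phase, duplicate replication;
* mixture response curves — Loewe-additive capture with a single antagonism
  parameter lambda: f = S/(lambda + S) where S is the Loewe sum, so
  lambda = 1 is exact additivity (f = S/(1+S)) and the noiseless additivity
  index equals lambda.

Everything is driven by :class:`SimulationConfig`; the same seed always
reproduces bit-identical output (one ``numpy.random.default_rng(seed)``
stream per generator call).

Only the ratio ka/kc is identifiable from competition data; the latent
scales (rate constants, radical concentration) enter solely through the
radical flux ``radical_flux_umol_L_s`` and the per-solute ``ka_rel`` /
``kc_rel``, which live here and nowhere in the analysis layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assay_core import (
    EndpointPlate,
    KineticTrace,
    write_endpoint_csv,
    write_kinetic_csv,
)
from .benchmarks import (
    ABTS_CONTROL_ABS,
    CROCIN_CONC_UMOL_L,
    CROCIN_SLOPES,
    REFERENCE_IC50,
    censoring_cmax,
)
from .exceptions import CensoredInputError, InvalidParameterError
from .mixture_design import MixtureSpec, design_stock, loewe_sum

__all__ = [
    "KineticBlock",
    "MixtureBlock",
    "SimulationConfig",
    "default_conc_grid",
    "simulate_endpoint_assay",
    "simulate_kinetic_trace",
    "simulate_kinetic_panel",
    "simulate_mixture_response",
    "generate_fixture_set",
]

#: Factor above c_max at which a censored solute's latent IC50 is placed.
#: "No effect at the concentration used" is a bound, not zero activity.
CENSORED_IC50_FACTOR = 100.0


@dataclass
class KineticBlock:
    """Crocin-assay simulation parameters.

    ``radical_flux_umol_L_s`` is the constant radical generation rate R_g
    (µmol/L/s). Every generated radical is consumed by crocin or antioxidant,
    so the uninhibited bleaching rate is v0 = R_g (in molar units); the
    default makes v0 = 1.0e-4 AU/s at the crocin epsilon. ``ka_rel`` maps
    solute -> ka/kc (with kc_rel = 1), the only identifiable combination.
    """

    crocin_umol_L: float = CROCIN_CONC_UMOL_L
    epsilon_M_cm: float = 13726.0
    path_cm: float = 1.0
    radical_flux_umol_L_s: float = 1.0e-4 / (13726.0 * 1e-6)
    kc_rel: float = 1.0
    ka_rel: dict[str, float] = field(default_factory=lambda: dict(CROCIN_SLOPES))
    t_lag_s: float = 60.0
    duration_s: float = 600.0
    dt_s: float = 5.0
    noise_sd: float = 0.002

    @property
    def v0_au_s(self) -> float:
        return self.radical_flux_umol_L_s * 1e-6 * self.epsilon_M_cm * self.path_cm

    @property
    def start_abs(self) -> float:
        return self.crocin_umol_L * 1e-6 * self.epsilon_M_cm * self.path_cm


@dataclass
class MixtureBlock:
    """Mixture-response simulation parameters.

    ``lam`` (lambda) is the antagonism parameter of the capture model
    f = S/(lam + S): 1 = exact Loewe additivity, >1 antagonism.
    """

    spec: MixtureSpec
    lam: float = 1.0
    n_replicates: int = 3
    volume_grid_uL: np.ndarray | None = None

    def __post_init__(self):
        if self.lam <= 0:
            raise InvalidParameterError("lambda must be > 0")


@dataclass
class SimulationConfig:
    """All knobs of the generator, with the study's default conditions.

    ``true_ic50`` maps solute -> IC50 (µmol/L) or None for a censored
    (no-effect) solute; censored solutes are simulated with a latent IC50 of
    ``CENSORED_IC50_FACTOR`` x their c_max. Defaults: Hill slope 1, control
    absorbance 0.750 AU, blank 0, endpoint noise 0.005 AU, kinetic noise
    0.002 AU, triplicate endpoints, duplicate crocin runs.
    """

    seed: int
    assay_id: str = "ABTS"
    true_ic50: dict[str, float | None] = field(default_factory=dict)
    censored_cmax: dict[str, float] = field(default_factory=dict)
    hill_h: float = 1.0
    control_abs: float = ABTS_CONTROL_ABS
    blank_abs: float = 0.0
    noise_sd: float = 0.005
    n_replicates: int = 3
    conc_grid: dict[str, np.ndarray] = field(default_factory=dict)
    kinetic: KineticBlock = field(default_factory=KineticBlock)
    mixture: MixtureBlock | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.kinetic.duration_s <= self.kinetic.t_lag_s:
            raise InvalidParameterError("duration must exceed the lag")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_conc_grid(ic50: float, n: int = 8, span: float = 10.0) -> np.ndarray:
    """Log-spaced concentrations bracketing a true IC50 (ic50/span .. ic50*span)."""
    if ic50 <= 0 or span <= 1:
        raise InvalidParameterError("need ic50 > 0 and span > 1")
    return np.geomspace(ic50 / span, ic50 * span, n)


def _latent_ic50(cfg: SimulationConfig, solute: str) -> tuple[float, float | None]:
    """(latent IC50, c_max if censored) for one solute."""
    truth = cfg.true_ic50[solute]
    if truth is not None:
        return float(truth), None
    c_max = cfg.censored_cmax.get(solute)
    if c_max is None:
        c_max = censoring_cmax(solute)
    return CENSORED_IC50_FACTOR * c_max, c_max


def _solute_grid(cfg: SimulationConfig, solute: str) -> np.ndarray:
    if solute in cfg.conc_grid:
        return np.asarray(cfg.conc_grid[solute], dtype=float)
    latent, c_max = _latent_ic50(cfg, solute)
    if c_max is not None:
        # censored solute: probe up to the highest concentration tested
        return np.geomspace(c_max / 100.0, c_max, 8)
    return default_conc_grid(latent)


def simulate_endpoint_assay(cfg: SimulationConfig) -> EndpointPlate:
    """Simulate one endpoint plate for every solute in ``cfg.true_ic50``.

    Sample wells follow ``blank + (control - blank) * (1 - f(c)) + noise``
    with f(c) = c^h / (c^h + IC50^h); control and blank wells (also noisy)
    are included per replicate. Deterministic under the config seed.
    """
    rng = cfg.rng()
    window = cfg.control_abs - cfg.blank_abs
    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        rows.append((cfg.assay_id, rep, "", 0.0,
                     cfg.control_abs + rng.normal(0, cfg.noise_sd), "control"))
        rows.append((cfg.assay_id, rep, "", 0.0,
                     cfg.blank_abs + rng.normal(0, cfg.noise_sd), "blank"))
        for solute in cfg.true_ic50:
            latent, _ = _latent_ic50(cfg, solute)
            for conc in _solute_grid(cfg, solute):
                f = conc**cfg.hill_h / (conc**cfg.hill_h + latent**cfg.hill_h)
                ab = cfg.blank_abs + window * (1.0 - f) + rng.normal(0, cfg.noise_sd)
                rows.append((cfg.assay_id, rep, solute, float(conc), float(ab), "sample"))
    df = pd.DataFrame(rows, columns=["assay_id", "replicate_id", "solute",
                                     "conc_umol_L", "absorbance", "role"])
    return EndpointPlate(data=df, meta={"seed": cfg.seed, "noise_sd": cfg.noise_sd,
                                        "hill_h": cfg.hill_h})


def simulate_kinetic_trace(cfg: SimulationConfig, solute: str, conc_umol_L: float,
                           sample_id: str | None = None,
                           rng: np.random.Generator | None = None) -> KineticTrace:
    """One crocin bleaching trace at antioxidant concentration [A].

    A(t) = start - v * max(0, t - t_lag) + noise, floored at the blank
    level; v follows the competition rate law with the solute's ka/kc.
    """
    if conc_umol_L < 0:
        raise InvalidParameterError("concentration must be >= 0")
    k = cfg.kinetic
    if rng is None:
        rng = cfg.rng()
    if conc_umol_L == 0:
        v = k.v0_au_s
    else:
        ka = k.ka_rel[solute] * k.kc_rel  # ka_rel is ka/kc; scale is irrelevant
        denom = k.kc_rel * k.crocin_umol_L + ka * conc_umol_L
        v = k.v0_au_s * k.kc_rel * k.crocin_umol_L / denom
    t = np.arange(0.0, k.duration_s + k.dt_s / 2, k.dt_s)
    a = k.start_abs - v * np.maximum(0.0, t - k.t_lag_s)
    if k.noise_sd > 0:
        a = a + rng.normal(0, k.noise_sd, size=t.shape)
    a = np.maximum(a, 0.0)
    return KineticTrace(
        sample_id=sample_id or f"{solute}@{conc_umol_L:g}",
        solute=solute, conc_umol_L=float(conc_umol_L),
        crocin_umol_L=k.crocin_umol_L, time_s=t, abs_443=a,
    )


def simulate_kinetic_panel(cfg: SimulationConfig, solute: str,
                           concs_umol_L, n_replicates: int = 2) -> list[KineticTrace]:
    """Duplicate traces at several [A] plus the [A]=0 reference, one rng stream."""
    rng = cfg.rng()
    traces = []
    for rep in range(1, n_replicates + 1):
        traces.append(simulate_kinetic_trace(cfg, solute, 0.0,
                                             sample_id=f"{solute}_r{rep}_A0", rng=rng))
        for conc in concs_umol_L:
            traces.append(
                simulate_kinetic_trace(cfg, solute, float(conc),
                                       sample_id=f"{solute}_r{rep}_A{conc:g}", rng=rng)
            )
    return traces


def simulate_mixture_response(cfg: SimulationConfig) -> EndpointPlate:
    """Endpoint-style response of an IC50-proportioned mixture vs added volume.

    Capture fraction f = S/(lam + S), S the Loewe sum at the added volume;
    lam = 1 reduces to the exactly-additive f = S/(1+S). The dose column of
    the returned plate is the added stock volume in µL; the antagonism
    parameterization and lam are recorded in plate metadata.
    """
    if cfg.mixture is None:
        raise InvalidParameterError("config has no mixture block")
    mix = cfg.mixture
    for comp in mix.spec.components:
        if comp.individual_ic50_umol_L <= 0:
            raise CensoredInputError(f"{comp.solute}: censored component")
    rng = cfg.rng()
    window = cfg.control_abs - cfg.blank_abs
    if mix.volume_grid_uL is not None:
        volumes = np.asarray(mix.volume_grid_uL, dtype=float)
    else:
        v50 = mix.lam * mix.spec.final_volume_uL / (mix.spec.n * mix.spec.multiplier)
        volumes = np.geomspace(v50 / 8.0, min(v50 * 8.0, mix.spec.final_volume_uL), 8)
    rows = []
    label = "+".join(mix.spec.solutes)
    for rep in range(1, mix.n_replicates + 1):
        rows.append((mix.spec.assay_id or cfg.assay_id, rep, "", 0.0,
                     cfg.control_abs + rng.normal(0, cfg.noise_sd), "control"))
        rows.append((mix.spec.assay_id or cfg.assay_id, rep, "", 0.0,
                     cfg.blank_abs + rng.normal(0, cfg.noise_sd), "blank"))
        for vol in volumes:
            s = loewe_sum(mix.spec, float(vol))
            f = s / (mix.lam + s)
            ab = cfg.blank_abs + window * (1.0 - f) + rng.normal(0, cfg.noise_sd)
            rows.append((mix.spec.assay_id or cfg.assay_id, rep, label, float(vol),
                         float(ab), "sample"))
    df = pd.DataFrame(rows, columns=["assay_id", "replicate_id", "solute",
                                     "conc_umol_L", "absorbance", "role"])
    return EndpointPlate(
        data=df, dose_kind="volume",
        meta={"seed": cfg.seed, "lambda": mix.lam,
              "antagonism_model": "f = S/(lambda + S), S = sum(c_i/IC50_i)",
              "multiplier": mix.spec.multiplier,
              "final_volume_uL": mix.spec.final_volume_uL},
    )


# ---------------------------------------------------------------------------
# Full fixture set
# ---------------------------------------------------------------------------

def _spread_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def generate_fixture_set(seed: int, outdir) -> Path:
    """Emit a complete benchmark-shaped scenario as CSV/JSON fixtures.

    Writes endpoint plates for the ABTS and HOCl panels (published IC50s as
    ground truth, censored solutes included), duplicate crocin kinetic
    traces for the active solutes and Trolox, an exactly-additive
    quaternary ABTS mixture curve, a sub-additive binary crocin mixture
    (uric acid + phenol, lambda = 1.503) and a manifest recording seed,
    truth values and lambda. Same seed -> byte-identical directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _spread_seeds(seed, 5)
    manifest: dict = {"seed": seed, "files": {}, "truth": {}}

    for assay, sub_seed, fname in (("ABTS", seeds[0], "abts_endpoint.csv"),
                                   ("HOCL", seeds[1], "hocl_endpoint.csv")):
        cfg = SimulationConfig(seed=sub_seed, assay_id=assay,
                               true_ic50=dict(REFERENCE_IC50[assay]))
        write_endpoint_csv(simulate_endpoint_assay(cfg), outdir / fname)
        manifest["files"][fname] = {"kind": "endpoint", "assay": assay}
        manifest["truth"][assay] = {k: v for k, v in REFERENCE_IC50[assay].items()}

    kin_solutes = ["uric acid", "Trolox", "phenol", "p-cresol", "L-tyrosine"]
    traces = []
    for solute, sub in zip(kin_solutes, _spread_seeds(seeds[2], len(kin_solutes))):
        cfg = SimulationConfig(seed=sub, assay_id="CROCIN", true_ic50={})
        slope = CROCIN_SLOPES[solute]
        # probe [A]/[C] from 0.5/slope to 4/slope: brackets the 50% point
        concs = np.geomspace(0.5, 4.0, 5) * CROCIN_CONC_UMOL_L / slope
        traces.extend(simulate_kinetic_panel(cfg, solute, concs))
    write_kinetic_csv(traces, outdir / "crocin_kinetics.csv")
    manifest["files"]["crocin_kinetics.csv"] = {"kind": "kinetic"}
    manifest["truth"]["CROCIN_slopes"] = {s: CROCIN_SLOPES[s] for s in kin_solutes}

    abts = REFERENCE_IC50["ABTS"]
    quat = design_stock([(s, abts[s]) for s in
                         ("uric acid", "phenol", "p-cresol", "L-tyrosine")],
                        multiplier=2.0, final_volume_uL=300.0, assay_id="ABTS")
    cfg = SimulationConfig(seed=seeds[3], assay_id="ABTS",
                           mixture=MixtureBlock(spec=quat, lam=1.0))
    write_endpoint_csv(simulate_mixture_response(cfg), outdir / "mixture_abts.csv")
    manifest["files"]["mixture_abts.csv"] = {"kind": "mixture", "lambda": 1.0}

    crocin = REFERENCE_IC50["CROCIN"]
    binary = design_stock([("uric acid", crocin["uric acid"]),
                           ("phenol", crocin["phenol"])],
                          multiplier=10.0, final_volume_uL=2000.0, assay_id="CROCIN")
    lam = 1.503
    cfg = SimulationConfig(seed=seeds[4], assay_id="CROCIN",
                           mixture=MixtureBlock(spec=binary, lam=lam, n_replicates=2))
    write_endpoint_csv(simulate_mixture_response(cfg), outdir / "mixture_crocin.csv")
    manifest["files"]["mixture_crocin.csv"] = {"kind": "mixture", "lambda": lam}
    manifest["mixtures"] = {
        "mixture_abts.csv": {"components": quat.solutes, "multiplier": 2.0,
                             "final_volume_uL": 300.0,
                             "ic50s": {c.solute: c.individual_ic50_umol_L
                                       for c in quat.components}},
        "mixture_crocin.csv": {"components": binary.solutes, "multiplier": 10.0,
                               "final_volume_uL": 2000.0,
                               "ic50s": {c.solute: c.individual_ic50_umol_L
                                         for c in binary.components}},
    }
    manifest["antagonism_model"] = "f = S/(lambda + S)"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
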