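# antioxcap

Antioxidant-capacity analysis for in-vitro reactive-oxygen-species (ROS)
scavenging assays, built for panels of small endogenous antioxidants —
prototypically the uremic solutes (uric acid, *p*-cresol, phenol,
L-tyrosine, …) that accumulate in chronic kidney disease and are removed by
hemodialysis. The package covers the five classic model systems — ABTS•⁺
decolorization (734 nm), HOCl/OCl⁻ capture via TMB oxidation (655 nm),
superoxide via NBT/formazan (560 nm), H₂O₂ via TNB (412 nm), and the
crocin bleaching assay for peroxyl radicals (443 nm) — plus the use of the
IC50 as an analytical tool for designing and interpreting antioxidant
*mixtures*.

## What it computes

**Potency (IC50 ± SEM) with censoring.** Percent inhibition is
`100·(A_control − A_sample)/(A_control − A_blank)`; the dose–response model
is a 0/100-anchored four-parameter logistic,

    inhibition(c) = 100 · cʰ / (cʰ + IC50ʰ),    h ≥ 0.2 free,

with monotone-interpolation fallback, replicate-level SEM, and censored
results (`> c_max`) when no 50% effect is reached at the highest tested
concentration.

**Competitive kinetics (crocin bleaching).** With radicals generated at a
constant rate, the bleaching rate falls from v₀ to
`v = v₀·kc[C]/(kc[C] + ka[A])`, i.e. `v₀/v = 1 + (ka/kc)·[A]/[C]`. The
slope of v₀/v vs [A]/[C] is the relative capture capacity ka/kc; divided by
the Trolox slope it gives Trolox equivalents. The same traces yield
`%In = (1 − v/v₀)·100` and hence a kinetic IC50 (= [C]/(ka/kc) when the
model holds exactly).

**IC50-proportioned mixtures and Loewe additivity.** A stock with every
component at the same multiple of its IC50 keeps all components at equal
IC50 fractions on dilution. Under Loewe additivity the mixture reaches 50%
inhibition when Σ cᵢ/IC50ᵢ = 1 — each of n components at 1/n of its IC50,
contributing 50/n percentage points of capture (12.5% for quaternary, 25%
for binary mixtures) — and the additive projection of the mixture IC50 is
the mean of the individual IC50s. The additivity index
(observed total / projection) classifies the interaction as additive,
sub-additive or supra-additive.

**Synthetic data.** A seeded generator produces endpoint plates, kinetic
traces and mixture response curves with the exact models above plus
Gaussian absorbance noise, so every analysis stage can be validated by
generator/analyzer round-trips.

## Worked example

```python
import numpy as np
import antioxcap as ax

cfg = ax.SimulationConfig(seed=42, assay_id="ABTS", true_ic50={"uric acid": 16.75})
plate = ax.simulate_endpoint_assay(cfg)
res = ax.DoseResponseModel.from_plate(plate, "uric acid").fit()
print(res.summary())
```

```
Dose-response fit
==============================================
assay:        ABTS
solute:       uric acid
n points:     24  (3 replicates)
dose axis:    conc_umol_L
method:       FOUR_PARAM_LOGISTIC
IC50:         16.6959 +/- 0.2355 (SEM, 3 replicate fits)
Hill slope:   0.995
pooled IC50:  16.6909
R-squared:    0.9996
```

The triplicate plate was simulated with a true IC50 of 16.75 µmol/L and
0.005 AU noise on a 0.750 AU window; the fit recovers 16.70 ± 0.24 µmol/L
with a Hill slope indistinguishable from 1. A quaternary ABTS mixture
proportioned to the IC50s of uric acid, phenol, *p*-cresol and L-tyrosine
(stocks at 2× IC50: 33.5, 25.96, 7.98 and 10.46 µmol/L in 300 µL):

```python
spec = ax.design_stock([("uric acid", 16.75), ("phenol", 12.98),
                        ("p-cresol", 3.99), ("L-tyrosine", 5.23)],
                       multiplier=2.0, final_volume_uL=300.0, assay_id="ABTS")
mcfg = ax.SimulationConfig(seed=3, mixture=ax.MixtureBlock(spec=spec, lam=1.0))
mix = ax.simulate_mixture_response(mcfg)
rep = ax.mixture_report(spec, ax.build_inhibition_curve(mix, mix.solutes[0]))
print(rep.summary())
```

```
Mixture report (ABTS; 4 components, multiplier 2, final volume 300 µL)
============================================================
    solute  ic50_volume_uL  conc_at_ic50_umol_L  individual_ic50_umol_L  ratio_to_ic50
 uric acid           37.24                 4.16                   16.75           0.25
    phenol           37.24                 3.22                   12.98           0.25
  p-cresol           37.24                 0.99                    3.99           0.25
L-tyrosine           37.24                 1.30                    5.23           0.25
observed total at IC50:  9.67 µmol/L
additive projection:     9.74 µmol/L
additivity index:        0.993 (ADDITIVE, tau=0.1)
```

Each component sits at one quarter of its own IC50 at the fitted mixture
IC50 volume (~37 µL vs the additive prediction 300/(4·2) = 37.5 µL), and
the additivity index is 1 within noise — the exactly-additive reference
behaviour.

## Command line

`antioxcap simulate|ic50|crocin|mixture|report` — simulate fixture sets,
fit potency tables from endpoint CSVs, analyze crocin kinetics, and build
mixture additivity reports. See `antioxcap --help`; CSV dialects are
documented in `antioxcap.assay_core`.

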