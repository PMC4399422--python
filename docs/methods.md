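# Methods

This note documents the models implemented in `antioxcap`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducibility.

## Endpoint inhibition and the IC50

The endpoint assays (ABTS•⁺, HOCl/TMB, superoxide/NBT, H₂O₂/TNB) all reduce
to the same structure: a control well carrying the full (100%) reaction, a
reading blank carrying none, and sample wells at increasing antioxidant
concentration. Percent inhibition is

    I(c) = 100 · (A_control − A_sample(c)) / (A_control − A_blank).

This statistic is invariant to adding a constant offset to all three
readings, so a shared background subtraction cannot change it; per-replicate
controls and blanks are used so replicate-level drift cancels. Negative raw
inhibition (apparent pro-oxidant behaviour, normally noise) is preserved in
the raw value and clamped to 0 only for fitting, which stabilizes the
optimizer without discarding information.

The potency model is a four-parameter logistic with floor and ceiling fixed
at 0 and 100 and a free Hill slope bounded below at 0.2:

    I(c) = 100 · cʰ / (cʰ + IC50ʰ).

Fitting is nonlinear least squares (`scipy.optimize.curve_fit`, trust
region with bounds, IC50 initialized from the interpolated 50% crossing).
When the optimizer fails, or lands implausibly far (>10³×) outside the
tested range, the estimator falls back to monotone linear interpolation of
the lowest 50% crossing of the isotonic-regression-smoothed mean curve —
deterministic under noise-induced multiple crossings. The method used is
always recorded in the result.

Censoring: if the per-concentration mean inhibition never reaches 50%, the
result is reported as a bound (`> c_max`), never as a number. This mirrors
standard scavenging-panel practice, where weak solutes tested up to 10×
their uremic plasma level simply show "no effect at the concentration
used". Censored potencies are refused as inputs to mixture design.

The reported IC50 is the mean of per-replicate fits (triplicate for
endpoint assays, duplicate for the crocin assay) and its SEM is the
standard error across those replicate-level estimates; the pooled-data fit
is retained as a diagnostic. Replicate-level summaries match how potency
panels are conventionally reported (mean IC50 ± SEM) and give an honest
dispersion estimate without bootstrap machinery.

## Competitive kinetics (crocin bleaching)

AAPH thermolysis generates peroxyl radicals at a constant rate; crocin
(25 µmol/L working concentration, ε = 13,726 M⁻¹cm⁻¹ at 443 nm in DMSO)
and the antioxidant compete for them:

    v = v₀ · kc[C] / (kc[C] + ka[A])   ⇔   v₀/v = 1 + (ka/kc) · [A]/[C].

Rates are least-squares slopes of A₄₄₃(t) over a configurable window,
default 60–600 s: bleaching is linear after roughly one minute and traces
run ten minutes. Rates are sign-flipped to positive; a non-negative slope
is flagged as non-bleaching with v = 0. Rate *ratios* are computed in AU/s
(the extinction coefficient cancels); molar rates via the crocin ε are
available for reporting.

The competition plot (v₀/v vs [A]/[C]) is fit by ordinary least squares
with a **free** intercept rather than forcing the theoretical intercept of
1: a fitted intercept far from 1 (|intercept − 1| > 0.2 triggers a warning)
is diagnostic of model inadequacy that a constrained fit would hide.
Trolox equivalents are the ratio of a sample's slope to the Trolox slope.

The kinetic %In = (1 − v/v₀)·100 feeds the same IC50 machinery as the
endpoint assays; for data following the competition law exactly, %In is a
unit-Hill-slope logistic in [A] and IC50 = [C]/(ka/kc). This closed form is
the core oracle of the test suite. Two caveats are flagged and not
corrected: [A]/[C] uses nominal initial concentrations (crocin consumption
during the window slightly biases late-window slopes), and crocin-depletion
nonlinearity is outside the phenomenological competition equation.

## IC50-proportioned mixtures and additivity

Mixture stocks are designed with every component at the same multiple m of
its individual IC50 (`stock_i = m · IC50_i`, exactly). Adding volume V of
stock into final volume Vf holds every component at the identical IC50
fraction `m·V/Vf` — asserted to machine precision in the code.

The additive reference is Loewe-type with shared unit Hill slope: 50%
effect occurs when the Loewe sum S = Σ cᵢ/IC50ᵢ = 1. This is the unique
reference that simultaneously yields (i) each of n components at 1/n of its
IC50 at the mixture IC50, (ii) capture shares of 50/n percentage points
each, and (iii) the additive projection of the mixture IC50 (as a total
concentration) equal to the plain mean of the individual IC50s. The
projection is generalized from the binary mean formula to any n on that
basis.

The additivity index is the observed total concentration at the fitted
mixture IC50 divided by the projection; classification uses a configurable
band τ (default 0.10): additive within 1 ± τ, sub-additive above,
supra-additive below. τ = 0.10 was chosen because quaternary mixtures
behaving "virtually exactly" additively land within ~6% of 1 under this
model, while the clearly antagonistic binary peroxyl-radical mixtures land
at 1.26–1.50.

Display rounding: published mixture tables mix round-half-up and truncation
when printing to two decimals. Both conventions are implemented; raw values
are always kept at full precision, the convention is embedded in output
metadata, and displayed totals are sums of the displayed (2-dp) cells so
printed columns stay internally consistent.

## Synthetic-data generator

The generator emulates exactly the structures the analyzers assume — that
is deliberate: noise-free output inverts through the analysis stack
identically (the round-trip oracle), and noisy output tests estimator
behaviour under the stated error model.

* **Endpoint plates**: `A = blank + window·(1 − f(c)) + N(0, σ)` with
  f the Hill response; σ = 0.005 AU by default on a 0.750 AU window
  (the ABTS radical working absorbance, 0.750 ± 0.020), chosen so
  triplicate IC50 SEMs are of the same order as the smaller published
  SEMs. Controls and blanks receive the same noise. Default grids are 8
  log-spaced points spanning IC50/10 to IC50·10.
* **Censored solutes** are simulated with a latent IC50 of 100 × c_max
  (c_max = 10× the uremic plasma level from the packaged reference table):
  "no effect" is a bound, not a zero-activity mechanism claim. Their grids
  probe up to c_max, so maximum simulated inhibition is ~1%.
* **Kinetic traces**: radicals are generated at constant flux R_g and every
  radical is consumed by crocin or antioxidant, so v₀ = R_g in molar units
  and the competition law holds exactly; the default R_g makes
  v₀ = 1.0 × 10⁻⁴ AU/s. Traces start at ε·[C] (0.343 AU for 25 µmol/L
  crocin), bleach linearly after a 60 s lag, run 600 s at 5 s sampling
  with σ = 0.002 AU, and are floored at zero. Only ka/kc is identifiable;
  the latent scales live only in the simulation config.
* **Mixture responses**: capture fraction `f = S/(λ + S)` with S the Loewe
  sum at the added volume. λ = 1 gives exact additivity (f = S/(1+S));
  λ > 1 is antagonism. The parameterization was chosen for three
  properties: exactness at λ = 1, strict monotonicity of the fitted
  additivity index in λ, and the identity additivity-index = λ in the
  noiseless limit (so an index of 1.5 is simulated by λ = 1.5). The model
  and λ are recorded in output metadata.
* **Determinism**: each generator call derives one
  `numpy.random.default_rng(seed)` stream; identical seeds give
  bit-identical plates, traces and fixture directories.

What the generator does **not** emulate: instrument drift, pipetting error
correlated across wells, heteroscedastic or non-Gaussian absorbance noise,
crocin depletion curvature, radical-flux transients at reaction start, and
chemical interactions between mixture components beyond the single-λ
antagonism. Passing round-trip tests therefore demonstrates correctness of
the estimators under the stated model, not robustness to every artifact of
real plate-reader data.

## Problem sizes and numerical choices

The validation suite uses desk-scale simulation sizes chosen to keep the
whole suite fast while leaving Monte-Carlo error well below the asserted
tolerances: 200 triplicate curves for stochastic IC50 recovery, 50 curves
for the independent grid-search oracle (10⁴ log-spaced IC50 values × 49
Hill slopes, direct SSE scan sharing no code with the fitting path), 100
replicates for additive-mixture recovery, and 60 runs for censoring
detection. Optimizer bounds are IC50 ∈ (10⁻¹², ∞), h ∈ [0.2, 10];
isotonic regression uses `scipy.optimize.isotonic_regression`; OLS with
inference uses `scipy.stats.linregress`. Beer–Lambert conversions are exact
round-trips by construction. The default optical path is 1 cm and is
configurable everywhere, since microplate effective paths vary with fill
volume and are rarely reported.

## Known limitations

* The logistic fit assumes a monotone response; strongly non-monotone
  (e.g. pro-oxidant-at-high-dose) data will fall through to interpolation
  and should be inspected.
* SEMs across two replicates (crocin assay) are weakly determined; the
  result records the replicate count.
* The additive projection as "mean of IC50s" is specific to
  IC50-proportioned designs; it is not a general mixture prediction for
  arbitrary composition ratios.
* Published per-assay SEMs of potency panels are not reproducible from
  summary data and are not targeted; only mean potencies are.
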