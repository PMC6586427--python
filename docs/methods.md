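# Methods

## Scope and model

The package estimates how temperature scales ecosystem-level quantities in a
regression-design mesocosm experiment with three trophic structures (A,
AG, AGP) crossed with a continuous temperature gradient (heater power 0–450
W in 50 W steps).  All temperature effects are modeled on the inverse
thermal energy scale 1/*kT* (eV⁻¹, *T* in Kelvin; Celsius only at the I/O
boundary), so that a ln-linear slope is interpretable as a
Boltzmann–Arrhenius temperature dependence.  One helper
(`activation_energy_from_slope`) owns the sign convention: *E* = −slope, so
rates that accelerate with warming have positive *E* and declining standing
stocks negative *E*.

## Oxygen fluxes

NEP is the daytime dissolved-oxygen gain and ER the overnight loss, each
divided by the interval length and converted with *z* = 31.25 µmol/mg.
Because saturation oxygen falls with temperature, the observed change is
corrected by the change in equilibrium concentration between the two
bounding readings before conversion; both fluxes are reported as absolute
values with the signed values kept as diagnostics.  The saturation model is
[O₂]ₑ(T) = exp(7.7117 − 1.31403 · ln(T + 45.93)) (T in °C), which
reproduces the expected ≈1 mg/L decrease per 5 °C of summer warming.  A
"literal" mode evaluating exp([O₂]water − [O₂]sat·ln(T+45.93)) with
user-supplied constants is retained for auditability only: that printed
form is dimensionally incoherent for typical inputs (exponent ≈ −25 at
20 °C) and is never used by default.  Bracketing choice: *z* multiplies the
whole corrected oxygen difference, then the interval divides, giving
µmol L⁻¹ h⁻¹.  Closed tanks are assumed: no reaeration term.

## Covariate construction

Within-subject mean centering decomposes each row's 1/*kT* into
`x_within` (deviation from the tank's mean over its analyzed weeks) and
`x_between` (tank mean minus grand mean).  The grand mean is the mean of
tank means, so tank-level `x_between` values average to zero even with
unbalanced data (e.g. the 219-row flux designs).  Responses are
ln-transformed; chlorophyll zeros are dropped and counted rather than
offset, while zooplankton counts — which are legitimately zero — use
ln(x+1).  Trophic-cascade strength is ln(chla_AGP/chla_AG) per (power,
week) pair, defined only when both paired tanks have positive chlorophyll;
its model uses 1/*kT* centered within power level, mean-centered numeric
week, and a random intercept per power level.

## Mixed models and model selection

All candidate models are Gaussian random-intercept LMMs estimated by
maximum likelihood (not REML), because the sets compare models differing in
fixed effects and the likelihoods must be commensurable.  The ln-response
family uses a ten-model nested ladder over {within, between, treatment,
treatment×between, treatment×within, within×between}; every subset respects
marginality (interactions require their main effects).  The parameter count
for AICc is fixed effects + 2 variance components, which reproduces the
conventional df accounting for this model family (full model: 10 fixed + 2
= 12).  AICc = −2logL + 2p + 2p(p+1)/(n−p−1); Akaike weights are
exp(−δ/2) renormalized; δAICc < 2 defines an equivalence set over which
coefficients may be conditionally model-averaged (weights renormalized over
the models containing the term).

Numerical care: `statsmodels` MixedLM's default optimizer can fail or stall
near the zero boundary of the group variance.  `fit_lmm` therefore tries
Powell, CG and BFGS in turn and always compares against the closed-form
var_group = 0 boundary solution, keeping whichever likelihood is highest
(cross-checked against lme4 ML fits on identical data).  A rank-deficient
design raises an error naming the offending columns; a single group, or an
explicit `zero_group_variance` flag, reduces to ML OLS.

## Pooled activation energies and intervals

For treatment *t*, the between-ecosystem slope is β₂ + β₅[t] and the
intercept β₀ + β₄[t]; the within-ecosystem slope at a between-covariate
value *x* is β₁ + β₃·*x* + β₆[t] (default *x* = 0, the grand-mean
temperature).  CIs come from the composite contrast over the fixed-effect
covariance, half-width = crit · √(cᵀVc).  The primitive default is the
normal 1.96 multiplier; the pipeline itself passes a small-sample df —
tanks per treatment minus the two between-level parameters (here 10 − 2 =
8) — because the between-ecosystem information is carried by a handful of
tank means, and Monte-Carlo calibration shows the normal multiplier
undercovers (≈0.90) where t(8) achieves ≈0.95.  The trophic-cascade
temperature dependence at a chosen week is β₁ + β₃·week; optionally a power
level's random-intercept BLUP can be added to the pooled slope — this
"fixed effects plus random effect" combination is one deliberate
interpretation of an underdetermined construction and is flagged as such in
the docstring.

## Synthetic experiment generator

The generator emulates the study design rather than any particular dataset:

* **Temperatures.** Weekly tank means = 23.9 °C baseline − 1.2 °C/week
  seasonal decline + (6.4/4.5) °C per 100 W heater offset + weekly weather
  noise (SD 1.5 °C) shared by the three treatments at a power level (paired
  tanks share a thermal environment).  This puts tank means on a
  19.7–26.1 °C gradient with within-tank SD ≈ 3.1 °C.
* **Chlorophyll.** ln chla follows the centered-covariate model with
  treatment-specific between slopes: A 1.30, AG 1.30 + 4.0, AGP 1.30 + 0.0
  (slopes on 1/*kT*; AG's total of 5.3 eV makes chlorophyll span roughly
  three orders of magnitude per 10 °C of between-ecosystem warming, the
  regime in which a strong temperature-dependent trophic cascade appears).
  The within slope is −0.52.  The within×between and treatment×within
  interactions default to zero, so the generating model is the ladder's
  model 7 term set.
* **Fluxes.** Latent ln NEP and ln ER follow the same structure (between
  slopes −1.40 and −1.32: fluxes accelerate with warming).  Diel DO
  profiles are constructed by inverting the corrected flux estimators —
  dawn DO anchored at saturation for the dawn temperature — so the
  estimators return the latent fluxes to machine precision; 21 of 240 diel
  records are then dropped at random (missing-data realism).
* **Zooplankton.** Poisson counts per 10 L in AG/AGP tanks, weeks 4–9
  (120 observations in 20 tanks): *Daphnia* with no temperature trend and a
  −0.23 predator effect on ln density; copepods declining with warming
  (slope +1.21 on 1/*kT*).  The count distribution is a modeling choice;
  no distribution is implied by the emulated design.
* **Noise.** Tank random-intercept variance 0.01 and residual variance
  0.12 (ln scale).  These are deliberately modest: they were chosen, once,
  so that the 10-tanks-per-treatment between-ecosystem slopes are estimable
  with per-replicate SE ≈ 0.17 eV and the ML variance components sit in a
  well-estimated regime, making the parameter-recovery study a sharp test
  of the estimation chain.  Real mesocosm data are noisier; passing
  recovery here demonstrates correctness of the machinery, not expected
  precision on field data.
* **Determinism.** One root seed spawns named substreams per component
  (temperature, chlorophyll, flux, zooplankton, missingness), so output is
  byte-identical under a fixed config and changing one component's settings
  leaves the others' draws untouched.

What the generator does **not** emulate: consumer–resource population
dynamics (effects are statistical, not mechanistic), taxonomic composition,
body-size distributions, temporal autocorrelation beyond the shared
seasonal trend, and non-Gaussian residual tails.  Tests passing on
synthetic data therefore validate the estimators and inference machinery,
not ecological realism.

## Parameter recovery

`mesotherm.recovery.recovery_study` repeats the full chlorophyll analysis
on fresh replicates (default 100; replicate seeds derived from one root
seed and kept below 2³¹): generate → center → fit the ten-model set → pool
the full model's between-treatment slopes with t(8) intervals.  It reports
the mean error of the pooled *E* against the generating values, empirical
95% CI coverage, and how often a model whose terms contain the generating
set ranks within δAICc < 2.  At the default conditions this yields |bias|
< 0.01 eV, coverage ≈ 0.94–0.96, and model identification in every
replicate; one hundred replicates run in about a minute on one CPU, a size
chosen to keep the whole validation suite fast while leaving Monte-Carlo
error on the bias estimate near 0.02 eV.

## Known limitations

* ML variance components are biased low with few groups; the t(8) pooling
  interval compensates for the dominant effect, but intervals on variance
  components themselves are not provided.
* Conditional model averaging reports point estimates only (no averaged
  intervals).
* The cascade model's temperature term is centered within power level, so
  between-power temperature signal is absorbed by the random intercepts;
  cross-power cascade temperature dependence should be read from the
  treatment×between interaction of the chlorophyll model instead.
* The "literal" saturation mode exists for auditability and should not be
  used for estimation.
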