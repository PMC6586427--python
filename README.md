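# mesotherm

Temperature dependence of community biomass, trophic cascades, and diel
oxygen metabolism in experimental mesocosms.

`mesotherm` is a reusable analysis pipeline for regression-design warming
experiments: a set of independent aquatic ecosystems held at different
temperatures and trophic structures — algae only (A), algae + grazers (AG),
algae + grazers + predators (AGP) — observed weekly for chlorophyll *a*,
dawn/dusk/dawn dissolved oxygen, and zooplankton counts.  It is written for
community ecologists who want to estimate how temperature scales ecosystem
functions and species interactions, in the framework of the metabolic theory
of ecology (MTE).

## The model

Per-capita metabolic rates follow the Boltzmann–Arrhenius relation
*b* = *b*₀ e^(−*E*/*kT*) *m*^α, with activation energy *E* (eV), Boltzmann
constant *k* = 8.617×10⁻⁵ eV/K, and mass-scaling exponent α.  At the
ecosystem scale a rate *B_R* (e.g. net ecosystem production, NEP, or
ecosystem respiration, ER) is

*B_R* = *b*₀(*T_c*) · e^(−*E*(1/*kT* − 1/*kT_c*)) · *M_B* · ⟨*m*^(α−1)⟩,

where *M_B* is total biomass density and ⟨*m*^(α−1)⟩ = Σ*m*^α / Σ*m* corrects
for the size structure of the community.  Taking logs linearizes the model:
a ln response is regressed on inverse temperature 1/*kT*, and the reported
temperature dependence is *E* = −slope.

The pipeline implements the full chain:

1. **Flux estimation** — NEP and ER (µmol O₂ L⁻¹ h⁻¹) from dawn/dusk/dawn
   dissolved-oxygen profiles, with a correction for the change in
   equilibrium (saturation) oxygen between the bounding temperatures.
2. **Covariate assembly** — within-subject mean centering splits 1/*kT*
   into a within-ecosystem component (weekly deviations from the tank mean)
   and a between-ecosystem component (tank mean minus grand mean), so
   short-term and cross-ecosystem temperature effects get separate slopes.
   Trophic-cascade strength is the log ratio ln(chla_AGP / chla_AG) for
   tanks paired by heater power.
3. **Inference** — nested sets of Gaussian random-intercept mixed models
   (ML), ranked by AICc with Akaike weights, optional conditional model
   averaging, and pooling of coefficients into composite per-treatment
   activation energies with confidence intervals.
4. **Synthetic experiments** — a seeded generator that emulates the whole
   study design (30 tanks = 10 power levels × 3 trophic treatments, weeks
   2–9, declining seasonal baseline, missing diel records, Poisson
   zooplankton), with the generating truth serialized so parameter recovery
   is exactly measurable.

## Worked example

```sh
mesotherm simulate --seed 1 --outdir demo
mesotherm fluxes  --input demo/dataset.csv --output demo/with_fluxes.csv
mesotherm analyze --input demo/dataset.csv --outdir demo/results
```

prints

```
wrote 240 rows (30 tanks) to demo/dataset.csv
219 of 240 rows have flux estimates; 21 diel series missing
phyto_biomass: 10 models on 240 observations; best PBF (w=0.75)
nep: 10 models on 219 observations; best NEP7 (w=0.67)
er: 10 models on 219 observations; best ER7 (w=0.85)
cascade: 5 models on 80 observations; best TCmF (w=0.52)
...
wrote pooled activation energies for 9 treatment-response pairs
```

240 ecosystem-weeks were generated; 21 diel oxygen series are missing, so
the flux models fit 219 rows.  The chlorophyll model set selects the full
model (PBF, Akaike weight 0.75), and `demo/results/pooled_effects.csv`
contains the pooled between-ecosystem temperature dependences, e.g. for
chlorophyll (eV, with 95% CI):

| treatment | E | CI |
|---|---|---|
| A | −1.13 | (−1.45, −0.80) |
| AG | −5.28 | (−5.60, −4.96) |
| AGP | −1.21 | (−1.54, −0.89) |

Negative *E* means biomass declines as ecosystems warm; the grazer-only
(AG) communities lose chlorophyll far faster with warming than communities
with predators (AGP), i.e. the trophic cascade strengthens with
temperature.  These match the generating values (−1.30, −5.30, −1.30)
within their intervals.

The same machinery runs on real data: `load_dataset` accepts any CSV with
the canonical columns (see `mesotherm.assembly.CANONICAL_COLUMNS`) or a
column-mapping for other dialects.

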