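# springlipids

Statistical analysis of archaeal tetraether lipids (iGDGTs) across thermal
springs: which geochemical conditions drive membrane-lipid cyclization, and
where along the pH and temperature axes does crenarchaeol — the cyclohexyl-
ring-bearing iGDGT of the *Nitrososphaeria* — reach its highest relative
abundance?

Thermophilic and thermoacidophilic archaea tune the packing of their
membranes by adding cyclopentyl rings to their glycerol dibiphytanyl
glycerol tetraether lipids (iGDGT-0 … iGDGT-8). The package takes
per-sample lipid relative abundances and spring geochemistry (temperature,
pH, dissolved O₂, specific conductivity, ORP, Fe(II), sulphide) and runs
the full chain of analyses such a survey needs, from index computation to
optimum estimation, for both core-lipid (CL) and intact-polar-lipid (IPL)
fractions.

## The quantities at the core

**Ring Index** — the abundance-weighted mean cyclopentyl ring count,
computed in two variants. With crenarchaeol as a four-ringed member
(its fifth, cyclohexyl ring is not counted):

    RI₊ = [ G1 + 2·G2 + 3·G3 + 4·(G4 + Cren + Cren′) + 5·G5 + … + 8·G8 ]
          / [ G0 + G1 + … + G8 + Cren + Cren′ ]

and without crenarchaeol (numerator *and* denominator restricted to
G0…G8). Both lie in [0, 8] and are invariant to rescaling of the inputs.

**Crenarchaeol relative abundance** — Cren over the summed abundance of
all species (the isomer Cren′ counts in the denominator only, by default).

**Neutrality line** — the temperature-dependent pH of neutral water,
`pH_neutral(T) = 8·10⁻⁵·T² − 0.0208·T + 7.4692` on 0–100 °C, used for a
temperature-aware acid/alkaline classification (the conventional fixed
pH 7.0 split is the default for summary statistics).

**Statistics** — Spearman's ρ screen and simple linear regressions per
predictor; exhaustive all-subsets multiple linear regression on
standardized predictors (2⁷ − 1 = 127 models for the seven-analyte panel)
ranked by adjusted R²; binned summaries (0.5 pH units / 5 °C, bins
labelled by their minimum bound); and LOESS curves (tricube-weighted
local quadratic regression, span 0.75) with 95% pointwise confidence
envelopes whose grid argmax estimates the pH and temperature optima of
crenarchaeol production.

A synthetic spring-survey generator (`springlipids.synthetic_springs`)
reproduces the statistical structure these analyses assume — bimodal
spring pH, Fe(II) anticorrelated with pH, DO tied to temperature-dependent
O₂ solubility, zero-inflated crenarchaeol peaked at circumneutral pH and
moderate temperature — so the whole pipeline is testable without any
external data.

## Worked example

```sh
python analysis/01_simulate_surveys.py   # write synthetic surveys to results/
python analysis/04_model_search.py       # 127-model searches
python analysis/05_optima.py             # bins + LOESS optima
```

prints, among other things:

```
ri_with_cren: 127 models fitted; best subset ph+temperature (adj R² = 0.825, p = 1.6e-15)
  inclusion in top significant models: ph×10, temperature×8, sulfide×4, ...
ph: LOESS optimum at 7.28 with predicted abundance 0.160
temperature: LOESS optimum at 44.52 with predicted abundance 0.141
```

Read: on the 41-sample synthetic panel, every one of the ten best
significant models for Ring Index contains pH — spring acidity, not
temperature, dominates cyclopentyl ring counts — while on the 300-sample
survey the LOESS argmax recovers the generator's crenarchaeol optima
(configured at pH 7.4 and 46 °C) to within the expected sampling noise.
Library use is one import away:

```python
from springlipids import ring_index, neutral_ph
ring_index({"G0": 0.5, "Cren": 0.5})                     # 2.0
ring_index({"G0": 0.5, "Cren": 0.5}, include_cren=False) # 0.0
neutral_ph(80.0)                                         # 6.3172
```

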