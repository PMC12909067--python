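# Methods

## Lipid indices

A lipid profile is the vector of relative abundances of iGDGT-0 … iGDGT-8
(`G0…G8`), crenarchaeol (`Cren`) and its isomer (`CrenIso`), normalized to
sum to 1; species a study did not report are stored as 0 (with a warning,
since compiled surveys report heterogeneous species sets). The Ring Index
is the abundance-weighted mean cyclopentyl ring count. Crenarchaeol and
its isomer carry weight 4 in the crenarchaeol-inclusive variant — the
cyclohexyl ring is deliberately not counted, as its effect on membrane
packing differs from that of cyclopentyl rings — and are excluded from
numerator and denominator in the other variant. The weight table is an
argument, so alternative conventions (e.g., counting the cyclohexyl ring)
are one call away. Both variants normalize internally, making them
invariant to uniform rescaling of the inputs; this and agreement with a
naive sum-of-products oracle on random Dirichlet profiles are tested.

Crenarchaeol relative abundance is `Cren` over the total of all species.
Whether the isomer belongs in the numerator is genuinely convention-
dependent across surveys; the default excludes it (the isomer is usually
minor and often reported separately), and `include_isomer=True` switches
convention. A sample is a *non-detect* when its crenarchaeol relative
abundance is exactly 0 in the input table; `detect_threshold` accommodates
trace-noise floors. Empty groups report undefined means (`None`) rather
than 0.

## Geochemistry

The neutrality line `pH_neutral(T) = 8·10⁻⁵·T² − 0.0208·T + 7.4692` is
treated as a given empirical polynomial, defined on 0–100 °C; evaluation
outside that window must be requested explicitly. Acid/alkaline
classification defaults to the fixed pH 7.0 split (boundary alkaline),
which matches how survey summary statistics are conventionally reported;
the temperature-aware neutrality-line split is available for exploration.

Field instruments report sulphide in μg/L (as S, molar mass 32.06 g/mol —
configurable, since colorimetric methods differ in basis) and Fe(II) in
mg/L (55.845 g/mol); conversions to mol/L are linear in the input.
Below-detection values (detection limits 5 μg/L sulphide, 0.01 mg/L Fe)
are flagged and imputed at half the detection limit by default — the
common geochemical convention — with `zero` and `exclude` policies
available. The raw flag is always retained in the sample table.

## Correlation screen

Spring geochemistry is heavy-tailed and often bimodal, so the first-pass
screen is Spearman's ρ on mid-ranks (scipy), with the t-approximation
p-value (n − 2 df) appropriate at the survey sizes involved (tens to
hundreds); an exact permutation p is available for n ≤ 9. A constant
vector makes ρ undefined: direct calls raise, and the batch screen
records a flagged invalid row so one degenerate analyte cannot abort a
heterogeneous compilation. Simple linear regressions standardize the
predictor (mean 0, SD 1) so slopes are comparable across analytes whose
magnitudes differ by orders; R² and p are unaffected by the scaling.
Missing values are deleted pairwise per test and the usable n is always
reported. Raw p-values at α = 0.05 are the default significance flag, as
is standard for this kind of exploratory screen; a Benjamini–Hochberg
column can be added and is clearly non-default.

## All-subsets model search

Every non-empty subset of the candidate predictors (127 for seven) is
fitted by OLS with intercept on standardized predictors; the response
stays on its natural scale (R² is invariant to response scaling).
Models are ranked by adjusted R² `1 − (1 − R²)(n − 1)/(n − p − 1)`,
which may be negative (worse than a horizontal line). Exact ties rank
the smaller subset first, then lexicographic names, so reports are
deterministic. Complete cases are taken per subset by default — each
model uses the maximum usable n, reported per model — with a listwise
option for strict comparability. Subsets that cannot be fitted (too few
cases, collinearity) are recorded as skipped, never dropped silently.
The "top models" view applies a model-level F-test gate at p < 0.05 and
keeps the ten best by adjusted R², tallying per-predictor inclusion.
Quadratic and interaction expansions exist behind flags on the fitting
routine; they are not part of the default search surface.

## Binned summaries and LOESS optima

Bins are half-open `[m, m + w)` with edges at integer multiples of the
width (0.5 pH units, 5 °C), labelled by their minimum bound; quartiles
use linear interpolation between order statistics (numpy's default,
type 7), so box statistics are reproducible bit for bit.

LOESS is implemented in-package: at each evaluation point the nearest
`ceil(span·n)` observations are fitted by weighted least squares of
degree 1 or 2 with tricube weights on scaled distance. Defaults are
span 0.75 and degree 2 — the long-standing defaults of the local-
regression tradition. Because each fitted value is a linear functional
l(x)'y, pointwise standard errors are `σ̂·‖l(x)‖` with
`σ̂² = RSS / (n − 2·tr L + tr L'L)` from the smoother matrix at the data
points, and intervals are t-based at 95%. The degree-1 smoother matches
statsmodels' lowess to machine precision on common inputs (tested), and
span 1/degree 1 reproduces exactly linear data; the interval
construction for a LOESS curve has no single canonical form, so a
case-resampling bootstrap would be the natural alternative where the
t-based envelope is doubted. The optimum estimate is the argmax of the
fitted curve on a regular grid (0.01 pH units / 0.1 °C), with a boundary
flag when the argmax sits at a grid endpoint; `compute_ci=False` skips
the O(n²) smoother pass when only the argmax is needed.

## Synthetic spring surveys

The generator draws, per sample and in a fixed documented order: a pH
from a two-component truncated-normal mixture on [1, 10.5] (acid-sulfate
mode N(3.0, 1.0) with weight 0.28, circumneutral/alkaline mode
N(8.0, 0.9) — the weights and modes put ~36% of springs below pH 7, the
proportion seen in compiled surveys); temperature uniform on 16–95 °C;
Fe(II) log-linear decreasing in pH (springs below ~pH 2 reach a few
10⁻⁵ M, alkaline springs fall below the 0.01 mg/L detection limit);
dissolved O₂ as a log-uniform saturation fraction times the tabulated
temperature-dependent O₂ solubility of fresh water, spanning roughly
1.6·10⁻⁷–6·10⁻⁵ M; ORP linear in pH (oxidising acid springs, reducing
alkaline ones) clipped to ±330 mV; lognormal conductivity spanning
~50–5400 μS/cm; and sulphide log-linear decreasing in ORP.

The crenarchaeol response surface is a product of Gaussians in pH and
temperature centred at pH 7.4 and 46 °C (widths 1.2 pH units and 22 °C,
amplitude 0.25 — chosen so the LOESS-predicted peak abundance lands near
0.12–0.15 after detection thinning and noise). Zero inflation comes from
a Bernoulli detection draw whose probability is logistic in the log
expected abundance (floor 0.05, ceiling 0.94); detected samples get the
expected fraction times lognormal noise (SD 0.6 in log), capped at 0.85.
The remaining abundance is allocated over G0…G8 by a Dirichlet whose
base measure is a binomial over ring counts with mean equal to a target
Ring Index drawn as `6.5 − 0.55·pH + N(0, 0.6)` clipped to [0, 8]; the
Dirichlet guarantees a valid composition with the intended mean ring
count, and its concentration (60) sets sample-to-sample scatter. The
isomer is a fixed 0.12 ratio carve-out of the crenarchaeol pool.
Below-detection Fe(II)/sulphide values are stored at half the detection
limit with the flag set, matching the analysis-side imputation so
fixtures round-trip exactly.

What the generator does *not* emulate: spatial/temporal autocorrelation
between springs sampled repeatedly, between-study measurement offsets in
compiled data, correlated detection between CL and IPL fractions, and
any taxonomy. Passing tests therefore demonstrate that the statistical
machinery recovers structure of this idealised kind at survey sample
sizes — not that real compilations are free of the confounds above.

## Problem sizes and determinism

The test suite and drivers use a 300-sample survey for distributional
checks and optimum recovery (20 seeds; 100 and 1000 samples for the
sample-size sweep) and a 41-sample, seven-analyte panel for the
127-model searches — the panel size at which such surveys are actually
collected. All randomness flows from `numpy.random.default_rng(seed)`;
identical configurations and seeds give byte-identical datasets and
pipeline outputs, and the run manifest written by `run_pipeline` echoes
every configuration field so a run can be reproduced exactly.

## Known limitations

- The t-based LOESS envelope ignores smoothing bias; near sharp peaks it
  is an approximation (the argmax, not the envelope, is the primary
  deliverable).
- The exact Spearman permutation p enumerates n! orderings and is
  restricted to n ≤ 9.
- The all-subsets search refits each subset from scratch (no QR
  updating); at k = 7 this costs well under a second per response, and
  the k ≤ 20 guardrail prevents accidental 2²⁰-model runs.
- `search` compares models fitted on per-subset complete cases; with
  heavy missingness, adjusted R² values across subsets are not strictly
  commensurable (use `listwise=True` there).
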