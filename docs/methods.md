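# Methods

## Model structure

The pipeline couples four statistical components over a dendritic stream
network whose unit of analysis is the *reach*: the stream segment draining
one incremental watershed (the catchment area gained between successive
junctions).

**Contemporary temperature model.**  JMMST (July mean daily maximum stream
water temperature, °C) is modeled as a linear function of reach-level
landscape covariates.  Subset selection evaluates candidate covariate sets
exhaustively and keeps the admissible set with the lowest AIC, where a set
is *admissible* only if every included term is significant at p < 0.05 in
its own fit.  The significance rule is enforced during the search (a
subset containing any non-significant term is discarded), not as a
post-hoc filter; with no admissible subset the intercept-only model is
returned with a warning.  AIC uses the Gaussian log-likelihood with the
maximum-likelihood variance, dropping additive constants:
`AIC = n·ln(SSR/n) + 2(k+1)`, with k counting intercept and slopes and the
extra parameter the residual variance.  Exhaustive enumeration is used up
to 16 candidates (2^16 fits); beyond that a greedy forward search over
admissible additions is used and flagged in the model's `selection_note`.
Full enumeration over all 2^32 subsets of the complete covariate table is
not tractable, so pipeline candidate lists are curated to the variables
with plausible mechanisms (defaults: JMMAT, WSAREA, LITHCAR, BFI, CCRIP,
PPTJUL, LITHSIL, TWI).

**Thermal sensitivity.**  The coupling slope β is the OLS slope of maximum
daily stream temperature on maximum daily air temperature over
June 1–August 31 (92 daily pairs).  β ≥ 0.275 defines high sensitivity;
the boundary is inclusive on the high side, and the probability cutoff of
the logistic classifier (0.50) is likewise inclusive — ties are
measure-zero but must be deterministic.  The logistic model is fitted with
high = 1 by default; an `orientation` flag supports coefficient tables
published in the opposite coding, since published tables for this problem
have signs consistent with low = 1 (e.g. smaller watersheds being *more*
likely low-sensitivity with a negative area coefficient).  The continuous
β model is fitted **only** on sites with observed β ≥ 0.275, and passing a
low-sensitivity site is an error rather than a silent filter: the model is
undefined off its stratum.  At projection time, predicted β is clipped at
zero so warming air can never cool a stream, and low-sensitivity reaches
receive zero warming.  Future JMMST is therefore monotone in the scenario
delta and exactly linear in it.

**ANC.**  Estimation is two-step: a binomial gate at 300 μeq/L, then a
linear model for the low-ANC stratum only (predictions may be negative —
acidified streams legitimately have negative ANC).  High-gate reaches are
above any biologically relevant acidity threshold and receive no
continuous estimate; habitat accounting assigns them the gate value, which
suffices because 300 > any admissible suitability threshold.  Raw linear
predictions are passed through a monotone nondecreasing recalibration
fitted by isotonic least squares on (predicted, observed) calibration
pairs, with a knot inserted at the 75 μeq/L pivot where prediction bias
historically changes sign.  Isotonic regression is the least-committal
monotone correction: it minimizes squared error over all nondecreasing
maps (so it can never do worse than the identity on the fitting pairs) and
it provably preserves the rank order of reaches by ANC, which keeps
threshold crossings coherent.  Outside the calibrated range the mapping is
clamped to its end values.  If the calibration pairs do not span the
pivot, there is no sign-flip to correct and the identity mapping is
returned with a warning.  Error is reported both overall and restricted to
predictions below 150 μeq/L, where accuracy matters most for impairment
mapping.

**Habitat accounting.**  Suitability requires strict inequalities
(JMMST < t_max AND ANC > anc_min); values exactly at a threshold are
unsuitable.  The four categories partition the (T, ANC) plane.  Summaries
follow the stressor-column convention: the "too warm" and "too acidic"
columns each include the dual-stressor overlap and the overlap is reported
separately, giving the exact per-unit identity
`warm + acidic − both + suitable = total`.  Lengths are carried at full
precision internally; published-style tables round lengths to whole km and
percents to 0.1, so identity checks against rounded rows use a ±2 km
tolerance.  ANC is held fixed across climate scenarios — only air
temperature changes — so suitable length is non-increasing in the warming
delta and non-decreasing in the thermal threshold (18 → 20 → 22 °C).

## Synthetic-watershed generator

The generator replaces the GIS stack (flow-routed DEMs, gridded climate,
soil/geology surveys, temperature loggers) with seeded draws that
reproduce the statistical structure the pipeline depends on:

- **Topology** is a random binary-merge tree: `n_headwaters` leaf
  catchments merge pairwise downstream to a single outlet, giving
  `2·n_headwaters − 1` reaches.  Topology is generated directly rather
  than routed from an elevation grid; the downstream stages consume only
  the link structure and area statistics.
- **Incremental areas** are log-normal, ln-scale parameters
  (−0.7551, 0.8526), calibrated jointly with rejection sampling above the
  0.5 km² headwater floor so the realized mixture has mean ≈ 0.9 km²,
  median ≈ 0.7 km², IQR ≈ 0.47–1.09 km².  Contributing areas accumulate
  exactly (conservation is testable by brute-force traversal).
- **Elevation** maps topological depth through its empirical rank
  (random tie-breaking within a depth class) onto the configured range,
  default 200–1700 m.  Rank-mapping spreads elevations uniformly while
  keeping every reach at or above its downstream neighbor.
- **JMMAT** declines with elevation at a lapse rate of −0.0065 °C/m with
  0.85 °C noise, so an elevation regression explains ≈ 0.92 of its
  variance, matching the tight air-temperature/elevation coupling of
  mountainous study regions.
- **ANC truth** declines linearly with elevation (default 470 μeq/L at
  the network base, −0.30 μeq/L per m) and rises with percent carbonate
  lithology (+1.5 per %), with 40 μeq/L reach noise, spanning the 50 and
  300 μeq/L thresholds at default settings.
- **Daily series**: per site, MDST_t = β·MDAT_t + intercept + ε with
  β ~ Normal(0.42, 0.15) truncated to [0.02, 0.96] and ε ~ N(0, 1 °C).
  MDAT follows the site's JMMAT plus a summer sinusoid and 2 °C daily
  noise.  The intercept anchors weakly coupled streams to groundwater
  temperature, taken as mean annual air temperature + 2 °C so the anchor
  declines with elevation.  True β and intercepts are returned so recovery
  tests need no re-derivation.
- **Management units** (3 forests × 3 districts by default) are contiguous
  subtrees carved to near-equal reach counts, mirroring districts nesting
  within forests.
- **Sites** are sampled uniformly over reaches (201 by default); the
  spatial placement of real logger networks is not modeled.

What the generator does *not* emulate: spatial autocorrelation of
temperature and chemistry along the network (reach noise is independent),
correlation between β and landscape covariates (β is drawn
independently, so the logistic sensitivity gate and the continuous β model
have no recoverable signal on default synthetic data and act as
pass-through stages there — their estimation machinery is exercised by
dedicated recovery tests with constructed signal), multi-year variability
(one synthetic summer), and real coordinate geometry.  Passing tests on
synthetic data therefore validate the estimation and accounting machinery,
not regional predictive skill.

## Numerical choices and edge cases

- TWI = ln(a / tan(slope)); a slope of exactly 0° is replaced by 0.001°
  before the tangent to avoid division by zero.
- Rank-deficient regression designs raise an error naming the collinear
  terms (identified from the near-null singular directions).
- Logistic fitting under complete separation falls back to an IRLS
  (binomial GLM) fit and sets a `separation_flag`; coefficients are
  reported with a warning rather than discarded.
- RMSE is the root mean squared residual (MLE convention, divide by n).
- Determinism: all generator randomness descends from one integer seed
  through independent seed-sequence streams per product (topology,
  covariates, ANC, series), so regenerating any product is bit-identical
  and adding a product does not perturb the others.  A pipeline rerun with
  the same config is byte-identical in every data output.
- The ANC calibration sample is a seeded uniform draw of reaches
  (default 500).  Because the low-ANC linear model is fitted by OLS on the
  calibration sample itself, its predictions are nearly unbiased and the
  isotonic correction is close to identity; predicted acidic stream length
  still underestimates true acidic length because prediction shrinkage
  pulls tail reaches toward the mean.  This mirrors the motivation for
  recalibrating externally developed ANC models, where the bias is larger.

## Problem sizes

Unit and property tests run on networks of 250–1,000 headwaters
(499–1,999 reaches); distributional checks on the area statistics use
5,000 headwaters (9,999 reaches).  Monte-Carlo recovery suites use 200
replicates at n = 200 (linear) and n = 500 (logistic).  The acceptance
script projects a 999-reach network.  These sizes give stable Monte-Carlo
behavior at interactive runtimes; all scale linearly if enlarged.

## Known limitations

- No spatial stream-network autocorrelation models; observations are
  treated as independent in all fits.
- Best-subset selection beyond the exhaustive limit is greedy and may
  miss the global AIC optimum (flagged in output).
- The recalibration's piecewise-linear form is a modeling choice; it
  matches the described sign-flipping bias structure without asserting a
  specific parametric form.
- Published coefficient tables ship without intercepts, so they support
  prediction *contrasts* only; absolute predictions require fitting.
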