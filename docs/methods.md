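# Methods

## The model

The package implements a discrete Bayesian belief network (BBN) for
comparing no-till (NT) against conventional tillage (CT) in winter wheat
production.  Eleven variables — four inputs (tillage system, soilscape,
seasonal rainfall, seasonal temperature), four intermediaries (carbon in
soil organic matter C-SOM, available water space AWS, precipitation
interception, biomass) and three outputs (grain yield, surface runoff,
GHG-CO₂ emissions) — are connected by 17 directed links into a DAG.  The
default edge list encodes the standard agronomic causal story: tillage and
the soil profile set the carbon stock and the water space; rainfall drives
biomass, water space and runoff; temperature drives biomass and emissions;
the carbon stock feeds yield, water space and emissions; water space feeds
biomass and runoff; biomass feeds interception and yield; interception
shelters against runoff.  AWS carries the most links of any node.  The edge
list is user-replaceable through the YAML model file, so an alternative
topology can be dropped in without code changes.

Continuous variables are discretized into ordered bands ("Very low" …
"Very high") with boundaries at empirical quantiles of the *training* data
(linear interpolation between order statistics).  The three output nodes
always have 5 bands, which the 5×5 confusion-matrix layout of the reference
evaluation requires; input/intermediary band counts are configurable
(default 5).  Intervals are half-open `[b_{k-1}, b_k)` with the last band
closed above, and out-of-range values clamp to the outermost bands, because
test seasons can exceed the training range.  Band midpoints are the
within-band medians of the training data and serve as the bands'
representative real values in variance-based sensitivity analysis.

CPTs are learned from complete discretized cases by Dirichlet pseudo-count
counting, `P(state|parents) = (count + w)/(row_total + w·K)` with uniform
pseudo-count `w` (default 1, i.e. Laplace smoothing; `w = 0` is maximum
likelihood with a uniform fallback for unobserved rows).  The smoothing
default matters in practice: the soilscape node has 15 states, so several
CPTs have parent combinations never observed in 1,110 training cases, and
an unsmoothed model can assign probability zero to legitimate test
evidence.  Inference is exact variable elimination with a greedy min-degree
ordering; the 11-node network is trivially tractable, so no approximate
method is provided.  Posteriors are renormalized after elimination to
absorb float drift; normalization is checked at 1e-9.  Predictions take the
posterior argmax with ties broken by the first declared state.  Missing
values are rejected (the emulated simulator output is complete); EM and
structure learning are out of scope.

## The synthetic season generator

The original model was parameterized from process-based crop-simulator
output (DSSAT/CERES-Wheat class) that is not publicly deposited, so a
seeded statistical emulator stands in for it.  It is a generator of
*seasonal aggregates*, not a crop model: no daily time steps, soil-layer
water cascades, phenology or texture regressions.  The default
configuration is the study grid: 3 soilscapes (PDPG6/7/8 with native
organic carbon 2.6/4.4/3.9 %) each at modeled OC 1/3/5/7 %, under NT and
CT — 30 experiments × 48 seasons (1975–2022) = 1,440 cases.  Seasonal
rainfall is gamma-distributed (mean 640 mm, sd 120 mm — lowland southern
England magnitudes) and shared across experiments within a run, as a single
catchment weather record would be; temperature is normal (10.2 ± 0.7 °C).

The structural equations (see `simulate.py`) implement, in order: C-SOM
decay (faster under CT: 0.6 %/season vs 0.15 %); AWS increasing in the
carbon stock with a small CT compaction penalty; biomass as a saturating
rainfall response × Gaussian temperature suitability × OC fertility factor
`(OC_eff/4)^0.32` × soilscape potential; interception increasing in
biomass; runoff as a rainfall fraction with a CT multiplier (1.9),
exponential shelter from AWS, linear shelter from interception, and a 2.5×
amplifier in extreme seasons (rainfall above its 90th percentile); yield as
harvest index × biomass × (1 − runoff stress), with an extra extreme-season
penalty in low-OC soils; emissions as background plus carbon turnover,
a CT multiplier (1.8) and a temperature response.  Noise is multiplicative
mean-one lognormal, cv 0.25, on biomass, runoff and emissions.  The
harvest index also carries seasonal noise (cv 0.08): harvest index varies
between real seasons, and without it the yield band would be an exact
function of the biomass band — an artifact no simulator exhibits.

Coefficient defaults were calibrated once so that per-experiment mean
yields fall inside the published 2,000–6,100 kg/ha envelope, and so that
runoff (≈2–15 mm/season means), emissions (NT ≈3,700, CT ≈8,000
kgCO₂eqv/ha) and AWS (≈130–500) sit in the reported ranges.  The generator
reproduces the qualitative findings of the system it emulates — paired CT
runoff and emissions exceed NT with a margin of more than two pooled
standard errors, and mean yield rises monotonically with OC — but it does
not reproduce per-soil values, year-to-year weather history, or the
reported tendency of high-OC soils to shed *more* runoff (in the emulator,
more carbon means more water space and hence less runoff).  Passing tests
therefore demonstrate the correctness of the analysis machinery under
realistic magnitudes, not agreement with any specific field dataset.

One structural point is deliberate: tillage affects runoff and emissions
*directly* in the generator (the multipliers), but the network's DAG routes
tillage through C-SOM and AWS only.  The learned model therefore recovers
tillage effects only through the carbon/water channel, exactly the
situation the original network faced against its simulator.  The resulting
NT-vs-CT shift of the top emission band is an order of magnitude smaller
than the runoff and yield shifts (fractions of a percentage point, as in
the reference analysis) and its sign is only stable when the model is fit
on the full 1,440-case run.

## Validation

Splits are chronological, never random: holdout trains on 1975–2011 (1,110
cases) and tests on 2012–2022 (330 cases); K-fold uses decade blocks K1
1975–1984 through K4 2005–2014, each tested after refitting on all other
years, plus a final train-K1–K4/test-K5 (2015–2022) row.  Banding schemes
and CPTs are refit per training partition — nothing from a test year enters
any fit, which the suite checks by perturbing test values within their
bands and asserting unchanged predictions.

Each test case is scored with all non-target variables as evidence (the
assumed case-testing configuration of the reference evaluation; an
"inputs only" policy is a config switch).  Reported metrics: the confusion
matrix and its error rate `100·(1 − trace/total)` (2 decimals), and three
proper scoring rules from the full posterior with `P_c` the probability of
the actual band — logarithmic loss `mean(−ln P_c)` (natural log, [0, ∞)),
quadratic/Brier loss `mean(1 − 2P_c + ΣP_j²)` ([0, 2]) and spherical payoff
`mean(P_c/√ΣP_j²)` ([0, 1]).  A zero-probability actual band is floored at
1e-12 for the log rule and counted in the report.

The three published holdout confusion matrices for this system are embedded
as reference data; the error-rate routine reproduces their reported
29.39 / 33.64 / 43.94 % exactly, implying at least 56 % accuracy for every
output.  On the synthetic run the yield error is comparable (≈28–32 %) but
runoff and emission errors are higher (≈65–76 %): the emulator's
within-band noise for those variables is larger than the original
simulator's, and their scoring-rule values remain well inside the
admissible ranges.  These synthetic error rates characterize the emulator,
not the original dataset.

## Sensitivity and scenarios

Sensitivity-to-findings ranks every other node by the expected reduction in
the target's variance `V(Q) − Σ_f P(f)·V(Q|f)` (band midpoints as values),
with mutual information (bits) and a "variance of beliefs"
`Σ_f P(f)·Σ_q [P(q|f) − P(q)]²` as companion columns.  The variance of
beliefs is a reconstruction of the third column of the classic Netica-style
report, whose exact formula is not published; it is isolated in one
function so it can be swapped.  All distributions come from exact
inference, and both statistics are verified against full-joint enumeration
in the tests.

Scenario influence compares posterior band distributions under named
evidence presets (NT, CT, favorable = NT + high-OC soil + moderate rain,
unfavorable = CT + low-OC soil + extreme rain) against the no-evidence
baseline, in percentage points per band.

## Numerical choices and limitations

* Probability tolerance 1e-9 for all normalization checks; renormalization
  after elimination.
* Quantile definition: numpy's linear interpolation — stated so the banding
  examples are reproducible.  Degenerate cuts (those that would leave an
  empty band, e.g. on a constant or all-zero column) are dropped with a
  warning and the band count shrinks.
* Declared state order is authoritative everywhere: CPT row layout
  (row-major over parents, last parent fastest), posterior vectors,
  confusion-matrix axes, argmax tie-breaks.
* The soilscape is one categorical node with 15 soilscape×OC states
  (matching the 15 profiles); a 3-state soilscape with a separate OC node
  would be an alternative encoding and can be expressed through the YAML
  model file.
* Season count follows the validation splits (1975–2022 = 48 seasons).
* Problem sizes throughout (1,440 cases, ≤6-node oracle networks, 100
  oracle queries) are the package's defaults and keep every analysis step
  in seconds on one core.
* Not modeled: N₂O/CH₄ emissions, slope/topography effects on runoff,
  within-season dynamics, real weather records — all outside the scope of
  the seasonal emulator.
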