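# Methods

`geosuit` implements a two-stage spatial analysis of species habitat
suitability: an ensemble of presence / pseudo-absence learners produces a
0–1000 suitability raster, and a set of geographical detectors quantifies how
environmental covariates — after a per-variable search for the best
discretization — explain the spatial pattern of that raster. A synthetic
landscape generator with fully known structure backs all testing and
benchmarking. This note records the models, the parameters that matter, the
numerical conventions, and the choices made where the design was genuinely
open.

## Synthetic landscapes

Covariates are Gaussian random fields: white noise convolved with an
isotropic Gaussian kernel (`smoothness` = kernel standard deviation in cells;
0 gives white noise), then standardized to zero mean and unit variance over
masked-in cells. A layer with a correlation target ρ to a partner is built as
`ρ·partner + sqrt(1−ρ²)·independent` and re-standardized, so the realized
sample correlation is close to ρ (±0.05 at 10⁴ cells). Smoothing was chosen
over an explicit geostatistical simulator because it gives controllable
spatial autocorrelation with no extra dependency; the cost is that the
field's effective number of independent patches shrinks as `smoothness`
grows, which widens the sampling fluctuation of any statistic computed on the
grid (this matters for the recovery benchmark below).

The true suitability surface is built on the logit scale:

    logit p = β₀ + Σ βᵥ xᵥ + s(x_step) + γ x_a x_b + ε,   ε ~ N(0, τ²)

where `s(·)` is a step function (strictly ascending breaks, one level per
stratum) supplying the stratified effect the detectors are designed to find,
and one optional pairwise product supplies an interaction. Noise enters on
the logit, not on p, so variance decompositions are exact: for a stratified
term with between-stratum variance B over cells and independent residual
variance V (all other terms plus τ²), the q-statistic of the true strata on
logit p converges to B/(B+V) as the grid grows. Occurrences are cells drawn
without replacement with probability proportional to p, reported at cell
centres.

Default generating conditions emulate an invasive forest pest: mean
prevalence ≈ 0.1 (suitable habitat a modest fraction of the region), one
dominant climatic driver, secondary vegetation/precipitation effects, a
stratified topographic effect, a human-activity interaction, logit noise
τ = 0.4, and one engineered covariate pair at ρ = 0.96 — strong enough that
the pairwise VIF 1/(1−ρ²) ≈ 12.8 exceeds the elimination threshold, so the
collinearity screen and the stepwise eliminator are both exercised. What the
generator does **not** emulate: sampling bias in occurrence records,
non-stationary covariate effects, anisotropic autocorrelation, and real
geographic boundaries (the optional mask is a smooth blob). Passing tests
therefore demonstrate correctness of the machinery under known, well-behaved
structure, not performance on real survey data.

## Occurrence handling

Records with unparseable or out-of-range coordinates are dropped (counted in
the log); exact duplicate coordinates collapse to the first record. Cells are
half-open, row 0 at the northern edge; a point exactly on a cell's eastern or
southern boundary belongs to the next cell. Thinning keeps one record per
occupied cell, chosen uniformly under a seed (the field-standard thinning
tools randomize this choice; we make the randomization explicit and
reproducible). Thinning is idempotent and its occupied-cell set is invariant
to input row order.

## Variable screening

Pearson correlations are computed over all masked-in cells (screening
concerns the environment, not any particular model's support). Pairs with
|r| > 0.8 are flagged for the report; removal is driven entirely by stepwise
VIF elimination: repeatedly remove the variable with the largest
VIF = 1/(1−R²) until all survivors are ≤ 10 (ties broken to the
lexicographically smallest name; non-finite VIFs from exact collinearity
count as +∞). Flagging and removal are decoupled because a flagged pair whose
correlation is below √(1−1/10) ≈ 0.949 does not by itself push VIF over 10;
the VIF criterion is the binding one.

## Ensemble suitability model

Twelve learner slots (GLM, GAM, MARS, FDA, RF, MAXENT, GBM, CTA, ANN, SRE,
RFD, XGBOOST) are backed by fixed-hyperparameter estimators (documented in
`geosuit.learners`); there is no automatic tuning. The MAXENT slot is a
penalized logistic regression on linear + quadratic + pairwise-product
features — a stand-in that keeps the roster slot's semantics at this scale,
not a MaxEnt implementation. SRE is a presence-only quantile envelope
(default 2.5% per tail) emitting {0,1}, which participates in the ensemble as
a probability.

Training data are presence cells plus `n_pa` background cells drawn uniformly
from masked-in, presence-free cells (drawn once per run seed). Evaluation
uses repeated stratified 80/20 splits with stratified k-fold CV inside each
training portion (defaults k = 10, 10 repetitions; the demo and benchmark
configurations scale these down, and the methods of every run are recorded in
its manifest). Metrics: AUC by the rank (Mann–Whitney) formulation with
midranks for ties, and TSS = sensitivity + specificity − 1 at the threshold
maximizing it over all distinct score values (ties → smallest threshold).
Learners pass the gate only with mean CV AUC strictly > 0.9 **and** TSS
strictly > 0.8 (both configurable); survivors are weighted proportionally to
the gating metric (TSS by default, AUC selectable) and refit on the first
repetition's 80% training portion. The ensemble probability is the weighted
mean of member probabilities, rendered as round(1000·p) with half rounded
away from zero; nodata cells carry −1.

Note on attainable skill: with pseudo-absences drawn uniformly from the
landscape, a fraction of background points falls in genuinely suitable cells,
which caps both AUC and especially TSS below what strongly clustered real
occurrence data can reach. Synthetic-landscape configurations therefore gate
at (0.85, 0.6) by explicit setting; the (0.9, 0.8) defaults reproduce the
reference design for data with real-data contrast.

Permutation importance is `mean over shuffles of 1 − r(pred, pred with the
column shuffled)`, clipped to [0,1]; response curves sweep one variable over
its observed range with all others at their medians.

## Geographical detectors

All detector computations use sums of squares (the population-variance
identity `N_h σ_h² = SS_h`), so q = 1 − SSW/SST is exact and free of
sample-versus-population ambiguity. The response is the ensemble suitability
(0–1000 rescaled to [0,1]) at all masked-in cells; an optional subsample
setting trades precision for speed on large grids.

**Discretization search.** Five methods × class counts 3–7 per variable;
the scheme with the highest q wins (ties → fewer classes, then method order
equal, natural, quantile, geometric, sd). Definitions, since the naming
conventions vary across tools:

- *equal*: k equal-width intervals over [min, max];
- *quantile*: breaks at the i/k sample quantiles (linear interpolation);
- *natural*: exact Fisher–Jenks minimization of within-class sum of squares,
  by an O(kn²) dynamic program over sorted values; above 2000 values the
  search runs on 2000 evenly spaced order statistics (assignment still uses
  the full data), which at that density is numerically indistinguishable
  from the exact optimum while keeping the search linear-time in practice;
- *geometric*: interval widths in geometric progression (ratio 2) summing to
  the range;
- *sd*: breaks at mean ± 0.5σ, ±1.5σ, … outward (the mean itself is included
  when an odd number of interior breaks is needed), clipped to the data
  range.

Bins are half-open (−∞, b₁], (b₁, b₂], …; empty classes are collapsed with
relabeling. Degenerate candidates (too few distinct values, single occupied
class) are logged and skipped.

**Factor detector.** q per variable at its optimal scheme. An optional
significance test refers F = (N−L)/(L−1)·q/(1−q) to a noncentral
F(L−1, N−L; λ) with λ = [Σ_h ȳ_h² − (Σ_h √N_h ȳ_h)²/N]/σ²; under a random
stratification λ ≈ 0 and null p-values are approximately uniform. It is off
by default because the q ranking, not a hypothesis test, drives the analysis.

**Interaction detector.** Overlay strata are the distinct label pairs.
Classification: q₁₂ > q₁+q₂ → Enhance-nonlinear; q₁₂ = q₁+q₂ (tolerance
1e−9, since exact equality is measure-zero) → Independent;
max(q₁,q₂) < q₁₂ < q₁+q₂ → Enhance-bi; min ≤ q₁₂ < max → Weaken-uni;
q₁₂ < min → Weaken-nonlinear. Because the overlay refines both inputs,
q₁₂ ≥ max(q₁,q₂) holds whenever no stratum is dropped; Weaken types are
reachable only through the minimum-stratum-size rule (default: strata under
10 observations are dropped from that computation, applied independently to
each stratification), which is standard detector practice on sparse
cross-classifications.

**Ecological detector.** F = [N₁(N₂−1)·SSW₁]/[N₂(N₁−1)·SSW₂] tests whether
two stratifications differ in within-stratum variance. The decision is "Y"
when F falls beyond either the upper-α or lower-α quantile of F(N₁−1, N₂−1),
so the verdict does not depend on the order in which the pair is given and a
perfectly explaining stratification (SSW = 0) on either side is flagged.
Because numerator and denominator share the same response values, the ratio
is far more concentrated than a true F variate and the test is conservative
under the null (rejection well below α in simulation).

**Risk detector.** Strata with fewer than 2 observations merge into the
nearest label. All stratum pairs get Welch t statistics with
Welch–Satterthwaite degrees of freedom and two-sided significance at α. A
stratum is *elevated* (*decreased*) when its mean is significantly above
(below) the pooled mean of all other strata at level α/L — Bonferroni across
the L stratum-level tests, without which the familywise false-flag rate for
L ≥ 3 strata necessarily exceeds α and "all intermediate under the null"
would fail by construction; otherwise *intermediate*. The trend statistic is
the Spearman rank correlation between stratum order (ascending breaks) and
stratum mean.

Circular covariates (e.g., aspect in degrees) are treated as plain linear
values, matching common detector practice; callers binning such variables
should be aware the discontinuity at 0°/360° is ignored.

## Pipeline and reproducibility

One YAML config drives the stage sequence simulate → thin → select → fit →
map → detectors. Every stage derives its seed as
`sha256(master_seed:stage_name)` (mod 2³¹−1), so adding a stage never
perturbs earlier stages' randomness, and each stage communicates with the
next only through its files (CSV tables; single-band ESRI ASCII-grid rasters,
a plain-text format that round-trips integer bands exactly, with a JSON stack
manifest). Re-running a config reproduces byte-identical CSVs and raster
values; a failing stage leaves its partial outputs plus a `FAILED` marker
naming the stage. The run manifest records seeds, per-stage counts and the
gate survivors.

## Benchmark problem sizes

The recovery benchmark uses 20 replicates of a 100×100 landscape
(smoothness 2, dominant linear coefficient 4, step levels ±1.2, τ = 0.4,
200 presences, 400 background points, four-learner roster, 5-fold CV, one
repetition), sizes at which the ensemble's held-out AUC and the stratified
driver's optimized q are stable enough to compare against their analytic
expectations while an entire run stays in the low minutes on one core. The
stratified driver's q is compared on the mean over replicates, because a
single smoothed realization's q fluctuates around B/(B+V) with the field's
effective patch count, not the cell count. Null-calibration checks use 500
replicates at N = 200. The demo configuration (40×40, 150 presences, reduced
folds) exists to exercise every stage quickly, not to estimate anything.

## Known limitations

- The MAXENT slot is a penalized logit, not MaxEnt; the GAM/MARS slots are
  spline-basis logits, not full backfitting/adaptive-knot implementations.
- Pseudo-absence contamination biases absolute skill downward on synthetic
  landscapes (see above); comparisons across learners remain meaningful.
- The geometric and sd discretizations follow the definitions above; other
  software may use different conventions for the same names.
- Geographic coordinates are treated as planar; no geodesic cell-area
  weighting is applied anywhere.
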