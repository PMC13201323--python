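# Methods

This note documents the models, defaults, and design choices behind
`ecoseasons`: what each stage assumes, which knobs matter, what the
synthetic data does and does not emulate, and where the design was
genuinely open.

## The synthetic study system

The generator emulates multi-year GPS telemetry of range-resident
ungulates and predators over a boreal-mixed-forest landscape, with known
ground-truth "seasons" so that the downstream pipeline can be validated
against truth it never sees.

**Landscape.** A smoothed Gaussian random field is thresholded at
class-quantile breakpoints, which matches requested land-cover
proportions to within cell-count granularity by construction and yields
spatially coherent patches (patch scale set by the smoothing length,
default 4 cells of 30 m). The default mixture is mainland-style boreal
cover: 44% mixed forest (plus the unallocated remainder), 17% deciduous,
11% coniferous, 9% shrubland, 7% wetland, 5% open water. Terrain (slope
in degrees, northness = cos aspect) derives from an independent smoothed
elevation field with ~400 m relief. Distance layers are exact Euclidean
distance transforms from a wavy one-cell shoreline along the southern
edge and a road polyline crossing the grid roughly perpendicular to it.
The perpendicular geometry is deliberate: parallel linear features make
the two distance surfaces near-duplicates of each other, which injects a
strong artificial covariance axis into every daily summary downstream.
Landscapes serialize as per-layer ESRI ASCII grids plus a JSON legend —
plain text, co-registered by construction.

**Movement.** Each individual is a biased correlated random walk on a
fixed schedule (default 4-h steps over 2 years of 365 days; leap days
are skipped). Within a regime, step lengths are Gamma(shape k, scale θ
meters) — θ is the gamma scale, so the mean step is kθ — and turning
angles are von Mises(0, κ) (uniform when κ = 0). Habitat preference uses
the standard discrete-choice approximation of a habitat-weighted
redistribution kernel: K = 30 candidate endpoints per step, one kept
with probability ∝ exp(w·z) where z are the endpoint covariates and w
the regime's selection weights on the log scale (per unit of raw layer
value). Candidates falling off the landscape are redrawn (10 attempts,
then a stuck-walker error with the offending position).

Central-place attraction multiplies each candidate's selection weight by
a Gaussian of SD `home_range_sd` (default 1,000 m) around the
individual's start point. This makes each walker a range resident, which
is how collared wolves, moose and deer actually behave, and it matters
statistically: without residency individuals drift across the landscape
and population daily means inherit strong day-to-day autocorrelation
that has nothing to do with seasonality. Setting `home_range_sd=None`
recovers the unbounded walk (used in availability-matching tests, where
occupancy must converge to landscape availability).

**Regimes as ground truth.** Regime day-windows are population-level and
shared across individuals — the seasons being emulated are states of the
population, not of individuals — and must tile the 365-day circular
year. The default two-season study condition is a 3:1 step-scale ratio
(summer θ = 300 m vs winter θ = 100 m, k = 2) with disjoint habitat
preferences (summer: wetland +1.5, deciduous +0.8; winter: conifer
+1.5, shrubland +0.8), switching at ordinal days 100 and 300. The null
condition is a single year-round regime (θ = 200 m, wetland +1.0).
Fixes are emitted with uniform ±15-min timestamp jitter and independent
5% failures, so the resampler always faces irregular intervals.

**Weather.** Daily mean temperature is a cosine with its minimum
(−17.8 °C) on ordinal day 15 and maximum (23.3 °C) half a year later,
plus N(0, 3 °C) noise. Snow depth is proportional to the magnitude of
the 15-day-smoothed sub-freezing temperature (2.5 cm per °C below zero,
with multiplicative noise) and exactly zero otherwise — so green-up
(ΔGDD) and snowpack are negatively associated by construction.

**What the generator does not emulate.** GPS position error; habitat-
dependent fix failure; correlated movement between individuals (packs);
dispersal, mortality mid-study, or collar turnover; inter-annual
variation in switch dates; temperature-dependent behavior. Passing
tests therefore demonstrate that the pipeline recovers population-level
regime switches of the simulated strength under clean telemetry — not
that it would date seasons to ±3 days on noisy field data.

## Track preparation

- Boundary-day rule: fixes within 7 days of capture or of track end are
  dropped (capture effects; uncertain mortality dates).
- Resampling is greedy and forward-only: keep the first fix, then the
  earliest later fix whose gap lies in [target−tol, target+tol]; when no
  such fix exists the chain restarts at the earliest fix beyond
  target+tol. The rule is idempotent and never looks ahead. Note one
  consequence: on a regular 1-h track at 4 ± 1 h the earliest admissible
  gap is 3 h, so thinning keeps every third hour.
- Turning angle at a fix is the signed heading change across the two
  preceding segments, in (−180°, 180°], counterclockwise positive;
  undefined values (first fix, first two angles, zero-length segments)
  are NaN, never 0.
- Covariate lookup is nearest-cell with the half-open convention
  x ∈ [left, right), y ∈ (bottom, top].
- Ordinal days live on a fixed 365-day circle; 29 February maps to day
  59 so that multi-year data pool cleanly.
- Land cover enters the daily matrix as per-class occupancy fractions
  (the mean of class indicators — a daily "average" of a categorical
  layer is otherwise undefined). Because the fractions sum to one, one
  class is linearly redundant in a way no pairwise correlation screen
  can see; the most-used class is marked dropped as the compositional
  reference (mirroring the RSF's open-water reference). Its column
  remains in the stored matrix so the sum-to-one invariant stays
  checkable.
- Transformation automates the usual quantile–quantile judgment: a
  non-negative column with sample skewness > 1 gets a square root, then
  every column is centered and scaled (sample SD, ddof = 1).
  Zero-variance columns are dropped with a recorded reason.
- The collinearity screen is iterative: while any pair has |r| ≥ 0.70,
  the member of the worst pair with the larger mean absolute correlation
  to all other retained columns is dropped (ties break to the later
  column). The drop order is recorded.

## Season clustering

**Screening.** HINoV clusters each variable alone (k_probe = 2 by
default) and scores it by the summed adjusted Rand agreement (topri) of
its partition with every other variable's. The classic read-off — a
visual scree of topri — is automated as the largest gap in the sorted
sequence, but that rule always cuts somewhere, even on pure noise. The
scores are therefore calibrated against a reference null in the spirit
of the gap statistic: multivariate Gaussian draws with the data's own
covariance, which carry the same inter-variable correlation but no
cluster structure. Only variables whose topri exceeds the largest
reference topri count as informative, and when none does, the pipeline
skips variable removal entirely. This guard exists because both removal
rules are otherwise self-fulfilling on structureless data: deleting the
"noisiest" columns, or columns that fail an ANOVA against a provisional
k-means partition of the same data, concentrates the matrix on its
leading covariance axis and can manufacture bootstrap-stable clusters
out of nothing.

The ANOVA screen itself supports two modes. `remove_nonsignificant`
(the pipeline default) removes variables that do not differ across a
provisional partition — screening out noise, consistent with the HINoV
rationale. `remove_significant` removes the variables that *do* differ;
it is implemented because the rule is sometimes stated that way, but it
deletes exactly the informative variables, so it logs a prominent
warning. The probe partition is a fixed-seed k-means at k_probe; using
"the k under evaluation" instead would be circular, since screening
precedes k selection.

**Choosing k.** The within-cluster sum of squares is computed for
k−1 … k+1 around the candidate range; the elbow is the k maximizing the
second difference (the sharpest bend), and the silhouette choice
maximizes the mean silhouette width. Both full curves are kept for
audit. When the two disagree, stability is assessed for both and the
smaller stable k wins — small-k parsimony, deterministically.

**Stability.** For each of `n_seeds` (default 10) outer seeds: fit a
reference k-means (k-means++ with 10 restarts, fixed seed stream), then
for each of B (default 5,000; the test and acceptance profile uses 200
× 3 seeds) bootstrap resamples of the days, refit and match every
reference cluster to the bootstrap cluster maximizing Jaccard overlap
among the days present in the resample. The bootstrap unit is the
ordinal day — the row of the matrix is the clustering observation. A
failed refit is retried up to 10 times, then scores zero for unmatched
clusters. The verdict is the strictest reading of the stability rule:
any cluster of any seed with mean Jaccard < γ = 0.75 voids clustering
and the pipeline reports "no seasonal states". When stable, the first
seed's assignment is carried forward.

**Smoothing and transition dating.** Daily labels are smoothed by a
5-day circular window mode (ties keep the day's own label, then the
smallest label id). Label runs shorter than the 8-day run threshold are
merged into their larger neighbor — no transition satisfying the run
rule exists for them. Per boundary, date A is the first day starting 8
consecutive new-state days scanning forward; date B is the day after
the last 8-day old-state run scanning backward; the transition is their
circular midpoint rounded half-up and becomes the first day of the new
state. Midpoints are computed along the shorter arc so winter states
spanning the year boundary date correctly. Days with no fixes inherit
the nearest labeled day's assignment before smoothing.

**PCA.** On the retained transformed matrix; loading columns are unit
norm; the percent variance of components 1–2 summarizes how much daily
space-use variation the state separation describes.

## Resource selection

The estimator is a deliberately simple stand-in for continuous-time
autocorrelation-adjusted machinery: a time-span-weighted Gaussian KDE
(Scott's-rule bandwidth; each fix weighted by half the gap to each
temporal neighbor) defines the utilization distribution on the landscape
grid, and isopleths are smallest superlevel cell sets holding 50%/95% of
mass — nested by construction. Every fit's metadata carries the
estimator description. Consequences of the simplification: no
autocorrelation adjustment of effective sample size (per-segment CIs are
anti-conservative) and grid-resolution-limited isopleths.

Segments are individual × state × year (a state spanning the new year
belongs to the year it began), buffered 14 days from every transition
date, and require ≥ 50 locations (a plain count; no variogram check).
Used fixes inside the isopleth, with time-span weights normalized to
mean 1, are contrasted with a uniform availability sample inside the
same isopleth at 10:1, carrying a large weight (1,000) so the logistic
fit approximates the Poisson point-process likelihood. Predictors:
land-cover dummies against the open-water reference (fixed 0),
northness, slope, and distances in km. A class absent from both point
sets is inestimable and excluded from pooling; separation or
non-convergence falls back to ridge-penalized IRLS (λ = 1, logged), with
covariance from the penalized Fisher information. AICc uses the number
of used points as the effective sample size.

**Pooling.** The population estimate per predictor is the weighted
arithmetic mean of per-segment coefficients. Default weights are
relative AICc (Akaike weights within the fit set); an equal-weight mode
exists because the AICc phrasing is ambiguous. AICc values from
different segments are not on a common likelihood scale, so relative
AICc weights often concentrate on one segment; the 95% CI therefore
uses the t distribution with the effective degrees of freedom implied
by the weights (n_eff − 1, n_eff = 1/Σw²), which widens honestly under
concentration instead of collapsing to a zero-width interval, and
reduces to the plain n−1-df mean CI under equal weights. Weights that
collapse numerically onto a single segment leave one effective segment
and the predictor is reported without a CI. Significance is CI-excludes-
zero; inference is valid to the extent the across-segment spread
captures the relevant uncertainty.

## Report arithmetic

ΔGDD is max(0, T − base) with base 1 °C — the operative plant-growth
threshold for the study latitude; the latitudinal correction that
produces it belongs to the weather-data provider and is exposed only
through `base_temp`. Accumulation resets each 1 January and missing
days stay missing. The ΔGDD–snow association is a plain Pearson r with
t = r√((n−2)/(1−r²)). Transition offsets are signed shortest-arc
differences between single dated transitions (positive = first
population later); they take explicit dates rather than state windows
because a printed season range and a printed transition date can
disagree by the one day of boundary-side convention.

## Problem sizes and profiles

Defaults follow the study design (B = 5,000 bootstrap replicates × 10
seeds). The test suite and the acceptance script use the light profile —
B = 200, 3 seeds, 12 individuals × 2 years, a 200 × 200 landscape — which
keeps a full pipeline run under ~10 s while leaving the stability
verdicts unchanged in every seeded condition we checked. RSF recovery
uses an 80 × 80 landscape and 250-fix segments, three segments per
pooled replicate.

## Known limitations

- The ±3-day transition recovery holds at the simulated signal strength
  (3:1 step-scale ratio, disjoint habitat weights); weaker or gradual
  transitions will date less precisely, and nothing in the pipeline
  models transition *gradualness*.
- The stability dichotomy (γ = 0.75) is a convention; values of minimum
  mean Jaccard near the threshold flip verdicts across seeds.
- k-means assumes roughly spherical clusters in the transformed space;
  strongly elongated seasonal structure could be split or merged.
- The RSF stand-in ignores autocorrelation; its per-segment CIs are too
  narrow, which is partly compensated at the population level by the
  across-segment t interval.
- All coordinates are projected planar meters; no geographic handling.
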