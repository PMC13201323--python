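# ecoseasons

Animal-defined seasonal space-use states from GPS telemetry.

Ecologists usually impose seasons on animal data from the calendar (winter
= December–February) even though what matters to a wolf or a moose is what
the *population* is doing: how far individuals move, which habitats they
occupy, when those patterns switch. `ecoseasons` delineates seasons from
the animals themselves — "seasonal space-use states" — and then asks how
habitat selection differs between them. Because real predator–prey
telemetry of this kind is rarely shareable, the package ships a
first-class synthetic-data generator with known ground-truth seasons, so
every stage of the pipeline is testable end to end.

## The method

**1. Daily space-use matrix.** Tracks (Movebank-style `individual_id,
timestamp, x, y` in a projected CRS) are resampled to 12 ± 2 h relocation
intervals; step length $\ell_t = \lVert x_t - x_{t-1}\rVert$ and signed
turning angle are computed per fix; landscape covariates (land-cover
class, slope, northness $=\cos(\text{aspect})$, distance to lake and to
road) are extracted at each fix; and everything is pooled into one row per
ordinal day $d \in \{1,\dots,365\}$ of population means (land cover as
per-class occupancy fractions). Columns are square-root transformed where
skewness exceeds 1, centered and scaled, and screened for collinearity
(one member of every pair with $|r| \ge 0.70$ dropped).

**2. Season clustering.** Variables are screened by HINoV — each variable
is clustered alone and scored by the summed adjusted Rand agreement
("topri") of its partition with every other variable's — calibrated
against a Gaussian reference with the data's own covariance, plus a
one-way ANOVA screen across a provisional partition. The number of
clusters $k$ comes from the elbow (second difference of within-cluster
sum of squares) and mean-silhouette criteria. k-means is then subjected
to a bootstrap stability check: for each of $S$ seeds and $B$ bootstrap
resamples of the days, each reference cluster is scored by its mean
Jaccard similarity to the best-matching re-fit cluster. If any cluster of
any seed falls below $\gamma = 0.75$, cluster formation is judged not
possible and the pipeline reports **no seasonal states** rather than
forcing a calendar. Otherwise daily assignments are smoothed by a 5-day
circular moving-window mode and each transition is dated as the circular
midpoint of the first chronological and last reverse-chronological runs
of 8 consecutive days in the new/old state. PCA summarizes how the
retained variables separate the states.

**3. Seasonal resource selection.** Within each (individual × state ×
year) segment — 4-h resampling, a ±14-day buffer around transition dates,
≥ 50 locations — a time-weighted Gaussian-kernel utilization distribution
yields core (50%) and home-range (95%) isopleths. Used fixes are
contrasted with available points sampled uniformly inside the isopleth in
a weighted logistic approximation to an inhomogeneous Poisson point
process (land cover with open water as the reference class, northness,
slope, distances; no interactions). Per-segment coefficients pool to a
population mean (AICc or equal weights) with t-based CIs; a predictor is
significant when its 95% CI excludes zero.

**4. Report arithmetic.** Daily growing-degree-day change
$\Delta\text{GDD}_d = \max(0, T_d - 1\,^\circ\text{C})$ proxies green-up
and is correlated with snow depth; transition dates of different
populations are compared as signed shortest-arc differences on the
circular year.

## A worked example

`examples/03_delineate_seasons.py` simulates 12 range-resident
individuals for two years whose movement switches between a long-step
summer regime (wetland/deciduous selection) and a short-step winter
regime (conifer/shrubland selection) at ordinal days 100 and 300, then
runs the full pipeline (light stability profile: B = 200, 3 seeds):

```
status: seasonal
variables retained after screening: ['occ_deciduous_forest', 'occ_shrubland', 'occ_wetland']
k by elbow: 2, k by silhouette: 2
k=2: min mean Jaccard 0.995 (stable at gamma=0.75)

recovered calendar (truth: summer 100-299, winter 300-99):
  cluster 0: days 100-299
  cluster 1: days 300-99

first two components describe 87.6% of daily space-use variation between states
```

The clustering recovers the hidden switch days exactly: every cluster is
highly stable (mean Jaccard 0.995 ≫ 0.75), and the dated transitions land
on days 100 and 300. Running the same pipeline on a single-regime
population instead returns `no seasonal states` — the stability check
correctly refuses to split structureless space use into seasons.
`examples/04_seasonal_resource_selection.py` continues to the selection
stage and prints the pooled summer coefficients, in which the truly
preferred classes (wetland, deciduous forest) come out significantly
positive. The other examples cover simulation, matrix preparation, and
the green-up/offset arithmetic.

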