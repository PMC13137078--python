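# Methods

## Predation risk from tether counts

A tether record is (site, deployment date, species, n_deployed,
n_recovered, n_consumed) with n_consumed ≤ n_recovered ≤ n_deployed.
Species-level predation risk is the proportion of *recovered* tethers with
missing prey, r = n_consumed / n_recovered. The denominator is recovered,
not deployed, because a tether that was never found again is uninformative
about consumption. Combinations that were not deployed, or from which
nothing was recovered, are explicitly missing (NaN) — never imputed as zero
at this layer. Deployments within a site are indexed 1..T in date order;
sites may have different calendars.

## Schedules and the KS distance

For each species × site, the risk series over the site calendar is turned
into a temporal *predation schedule*: weights proportional to risk,
normalized to unit sum. Normalization makes the comparison one of shape and
timing only — multiplying a series by a positive constant leaves its
schedule and all its KS distances unchanged. The corollary is that series
that are flat at *different* levels collapse to identical uniform schedules;
an un-normalized variant (`normalize=False`, cumulative raw risk) is
provided for analyses where level differences should register. The
normalized form is the default because the schedule-comparison method this
follows is defined on unit-mass distributions.

Interior missing deployments are filled by linear interpolation on the date
axis between adjacent observed risks; gaps at the calendar boundaries take
the nearest observed value. Fills are flagged `interpolated` and counted in
the pipeline manifest. Interpolation (rather than dropping dates) keeps the
comparison window identical across pairs. Series with fewer than two
observed values, or with all-zero risk, cannot define a distribution and are
excluded with a logged warning.

The KS distance between schedules a and b is sup |F_a − F_b| over the union
of their date grids, where F is the cumulative weight as a right-continuous
step function. No kernel smoothing is applied: the data are ~16 discrete
deployments and the step-ECDF supremum is exact. The statistic lies in
[0, 1], is symmetric, vanishes iff the schedules coincide, depends only on
date *order* (any strictly monotone re-mapping of a shared date axis leaves
it unchanged), and satisfies the triangle inequality (it is the sup-norm
distance between CDFs). `check_metric` nonetheless audits every unordered
triple of the computed matrix exhaustively, reporting the worst signed
excess D[i,k] − D[i,j] − D[j,k]; the tolerance is 1e−12 absolute in memory.
The pipeline audits the *serialized* matrix, whose entries are rounded to 12
significant digits, and widens the tolerance by the worst-case rounding of a
three-term sum (1.5e−12).

## Ordination and dispersion

PCoA eigendecomposes B = −½ J (D∘D) J (J the centering projector).
Eigenvalues with |λ| < 1e−8·max|λ| are treated as zero (configurable);
positive axes get coordinates scaled by √λ, negative axes "imaginary"
coordinates scaled by √|λ|. KS matrices are metric but generally not
Euclidean-embeddable, so some negative mass is expected; the eigen report
gives the negative share of total absolute eigenvalue mass and per-axis
shares under both conventions (relative to the positive sum, and relative to
total absolute mass). Axis signs are fixed so the first non-negligible
loading of each axis is positive, making serialized output reproducible.
The trace identity Σλ = tr(B) is asserted on every run.

Per-site dispersion follows the distance-to-centroid definition of
multivariate group dispersion: centroids are per-axis means over *all*
retained axes, and a member's squared distance is (squared Euclidean
distance on positive axes) − (squared distance on negative axes). Negative
corrected squares — possible with strongly non-Euclidean input — are
truncated to zero and counted. Group dispersion is the arithmetic mean of
member distances (the convention of the reference implementation, vegan's
`betadisper`, against which the tests cross-check); groups with fewer than
two members get a missing value. On Euclidean-embeddable input this reduces
exactly to ordinary distance-to-centroid, which the tests verify against
direct computation from raw coordinates.

## Variability and correlations

Community-level risk at a site-deployment is the pooled proportion
Σ n_consumed / Σ n_recovered across species — equivalently the
recovered-count-weighted mean of species risks. An unweighted-mean variant
(`pooled=False`) is available, since with unequal effort the two differ.
Community-level variability is the sample SD (n−1) of that series over
deployments with at least one recovered tether; species-level SDs use only
observed (non-interpolated) deployments, because interpolation exists solely
to complete KS grids. Sample SD throughout, so SD{a, b} = |a−b|/√2.

Pearson r uses the product-moment estimate with two-sided p from
t = r·√(df/(1−r²)), df = n−2. Spearman's rho is Pearson on average ranks;
for n ≤ 8 its two-sided p is exact, enumerating all n! permutations, else
the t approximation is used. Missing values are dropped pairwise. No
multiple-testing correction is applied; the report carries the number of
tests so users can apply their own. The default battery correlates
dispersion with community SD, each habitat mean (eelgrass cover, shoot
density, bare cover, macroalgae cover) with both, and each species' annual
SD with eelgrass cover and shoot density; species observed at fewer than
three sites are skipped with a logged note.

## Synthetic studies

The simulator draws n_recovered ~ Binomial(tethers, recovery_prob) and
n_consumed ~ Binomial(n_recovered, r_s(t)) from Gaussian seasonal curves
r_s(t) = baseline + amplitude·exp(−(t − peak)²/2w²) on a day axis counted
from 1 January of the study's first year. A Gaussian bump (not a circular
density) is adequate for a single-year window; staggered peaks are kept at
least 2w from the window edges. Default calibration, chosen once as
field-plausible: baseline 0.1, amplitude 0.5 (risk 0.1–0.6, the range
typical of epifaunal tethering data), width w = 35 days, recovery
probability 0.9, 20 tethers per species, 16 deployments at 22-day spacing
from mid-April, six sites (three with four species, three with three,
giving 21 series and 336 records), shared peak in mid-September.

The per-site parameter γ ∈ [0, 1] blends each species' peak between the
shared peak (γ = 0: coincident schedules, strongly seasonal community risk)
and evenly staggered positions (γ = 1: complementary peaks whose sum is
near-constant away from the window edges). Habitat surveys (11 dates ×
5 quadrats the following year) have mean eelgrass cover increasing linearly
in γ from 2% to 50%, shoot density 1.15 to 34.8 per 0.25 m², bare cover
falling 94% to 50%, with seasonal modulation and quadrat noise; macroalgae
cover is site-random and unrelated to γ. Randomness is one master seed
deriving an independent substream per (site, deployment, species) via a
stable hash, so adding a site never perturbs another site's draws.

What the generator does *not* emulate: spatial autocorrelation along
transects, predator-community dynamics, species-specific recovery rates,
and year-to-year habitat change. Passing tests therefore demonstrate that
the pipeline recovers the dispersion/stability/habitat sign structure when
the compensatory-timing mechanism is the true data-generating process — not
that field data obey that mechanism.

## Pipeline determinism

Every stage reads its inputs from the serialized artifacts and writes its
own, so re-running any stage from intermediates reproduces downstream
artifacts byte-for-byte. Floats are serialized at 12 significant digits;
normalized schedules are re-normalized on read (relative adjustment
< 1e−11). The manifest records the config digest (excluding the output
location), seed, package versions, and per-stage counts of interpolations,
exclusions and truncations — the analysis's silent choices, made auditable.

## Problem sizes

The test suite and acceptance script use the six-site default design
(21 series, 336 records) and 200 replicate studies for the sign-recovery
rates; KS/PCoA/dispersion oracles run on randomized schedules and point
clouds of up to 12–16 points. These sizes give Monte-Carlo rates stable to
well under the 95% acceptance thresholds while keeping a full run under a
minute.

## Known limitations

* The exact Spearman permutation p enumerates n!, practical only for n ≤ 8
  (the six-site design gives n = 6).
* Dispersion with heavy negative eigenvalue mass can truncate member
  distances; the truncation count should be checked before interpreting
  site comparisons.
* The ingest layer assumes one record per (site, date, species); replicate
  transects within a deployment must be pre-aggregated.
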