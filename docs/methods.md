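# Methods

## Model and estimation

The package treats a family as a single draw from a constant-rate
birth–death process conditioned on survival: a clade of crown age *t* (My)
holds *n* extant species with geometric probability
P(n) = (1 − β_t) β_t^(n−1), where β_t = (e^{rt} − 1)/(e^{rt} − ε),
r = λ − μ and ε = μ/λ.  β is computed as expm1(rt)/(expm1(rt) + (1 − ε)),
which is exact in the pure-birth limit (β = 1 − e^{−rt} at ε = 0, matched
to 1e−12 in tests) and stable as t → 0; past rt ≈ 700 the asymptotic forms
ln β ≈ −(1 − ε)e^{−rt} and ln(1 − β) ≈ ln(1 − ε) − rt avoid overflow.

Rates are assumed homogeneous only *within* a geological interval; interval
breakpoints are consumed as configuration (their inference from
rate-shift analyses is outside this package's scope).  Within an interval
the likelihood ℓ(r, λ) = Σ ln(1 − β_i) + (n_i − 1) ln β_i is maximized by
exhaustive search on a rectangular (r, λ) grid; ε is derived (ε = 1 − r/λ),
never gridded, and points with λ < r are skipped because they would imply a
negative extinction rate.  The canonical grid is r ∈ [0.0001, 0.2] in steps
of 0.0002 and λ ∈ [0.1, 100] in steps of 0.01; the pipeline front-end
truncates λ at 5/My as its practical default, because family-level fits
with any monotypic family present have vanishing likelihood at high λ
(1 − β → 0), so the confidence region never approaches the truncation.
Internally the sum is aggregated over unique ages (the likelihood depends
on the data only through per-age clade counts and richness sums), which
makes the ~10⁷-point canonical grid tractable; tests verify the maximizer
equals a naive per-point loop.  Ties are broken toward the smallest r, then
the smallest λ, so results are deterministic.

## Two uncertainty systems

**Profile-likelihood region.**  All grid points within `ci_log_units`
(default 1.0) of the maximum log-likelihood.  Parameter intervals are the
extremes of r and λ over this region, with μ = λ − r and ε = 1 − r/λ
deduced.  The region is stored compactly as, per retained r, the smallest
and largest λ within the threshold — sufficient because β_t is strictly
increasing in both r and λ at fixed t, so every β extreme over the region
is attained at a stored edge.

*Coverage caveat*: a 1 log-unit drop corresponds to a likelihood-ratio
threshold of 2Δℓ = 2, whose single-parameter asymptotic coverage is
P(χ²₁ ≤ 2) ≈ 84%, not 95%; simulation in this package reproduces that
(~76–84% depending on grid resolution).  The default follows the method's
published rule; users wanting calibrated 95% intervals should set
`ci_log_units=1.92`.

**Stochastic clade-size bounds.**  The 2.5%/97.5% quantiles of the
geometric law, k_upper(t) = ln(0.025)/ln β_t + 1 and
k_lower(t) = ln(0.975)/ln β_t + 1, kept real-valued.  Classification
compares n to the *widest* interval [min k_lower, max k_upper] over the
profile region at the family's age ("maximum width" policy), which unions
the two uncertainty systems and is conservative against false poor/rich
calls.  Bounds are never rounded to integers: rounding would manufacture
boundary flips, and the containment test n < k_lower / n > k_upper is
well-defined on reals.  A consequence worth knowing: k_lower > 1 for every
β ∈ (0, 1), so monotypic families always classify low — defensible, since
P(n = 1) = 1 − β < 0.025 whenever β > 0.975, which holds for realistically
old clades; bound coverage is only nominal (~95%, verified at 10,000 draws
in tests) when β is near 1, i.e. discreteness is negligible.

## Consensus and downstream tests

Per-dataset calls (low/predicted/high) aggregate to strict consensus
(poor/expected/high; all five datasets agree — families absent from any
dataset are ineligible) or majority consensus (≥4 agree); everything else
is undefined.  Category percentages are reported to one decimal of the
consensus-classified total.

Contingency analyses use uncorrected Pearson χ² (no Yates correction —
the published statistic on the duplication table matches the uncorrected
value) with Haberman adjusted residuals
(O − E)/√(E(1 − R/N)(1 − C/N)), flagged at |d| > 1.96 (α = 0.05 two-sided;
the cited residual method states no threshold, so the standard-normal
critical value is used).  Expected counts below 5 warn but do not switch
methods, matching the source analyses.  Trait batteries run tie-corrected
Kruskal–Wallis per trait with a single Benjamini–Hochberg pass across all
traits at q = 0.1; the realized p-threshold is reported rather than
hard-coded, and Dunn's pairwise z on mean ranks (tie-corrected pooled
variance, BH within trait) is computed only for significant traits.
Kolmogorov–Smirnov comparisons of median family ages are pairwise across
the three categories with asymptotic p-values, reporting each pair and the
maximum D.

Mating systems collapse per-family fractions to one label: Dioecious iff
every scored species is dioecious (takes precedence over other labels); SC
or SI iff >80% of scored species are in the class; an SI/SS fraction in
[0.2, 0.8] is the mixed SC-SI class (threshold equality assigned to the
mixed class, the conservative reading of strict inequalities); profiles
with no scored species, or too weak a signal for any class (SI/SS < 0.2
with SC ≤ 0.8), are Unknown.

## Geography

Occurrence cleaning keeps preserved-specimen/literature records with full
binomials and in-bounds coordinates, drops exact (taxon, lon, lat)
duplicates keeping the first, and honours a caller-supplied exclusion list
(crops, cultivated material); every rule logs its rejection count.
Per-family net diversification rates use the standard richness-and-age
estimators — stem: r = ln(n(1−ε) + ε)/t; crown:
r = [ln(n(1−ε²)/2 + 2ε + ((1−ε)/2)√(n(nε² − 8ε + 2nε + n) + 4ε²)) − ln 2]/t —
defaulting to stem at ε = 0 (these are nonnegative for n ≥ 1; reported
negative per-family rates in the motivating analyses are not reproducible
from any stated estimator, so the choice is explicit configuration).
The 1° grid uses half-open [i, i+1) cells via floor of the coordinates,
folding lon = 180 and lat = 90 into the last cell; each record contributes
its family's rate once and cells average over records.

Range categorization replaces the source's visual assessment with a
deterministic rule: highly_localized (all records inside one 10°×10°
window), localized (one realm), cosmopolitan (≥4 realms), widespread
(otherwise, i.e. 2–3 realms); thresholds are configurable and the realm
count stands in for continent count since realms are the only
spatial partition the pipeline requires.  Distribution pattern is disjunct
when single-linkage clustering on great-circle (haversine) distances finds
≥2 clusters at a 2,000 km gap (configurable); families beyond 2,000 records
are deterministically thinned before the O(n²) distance matrix.
Realm/biome membership itself is delegated to labels supplied on the
records (or any caller-side point→label classifier); ecoregion shapefiles
are deliberately not bundled.

## Synthetic data: what it does and does not emulate

The generator draws each family's age uniformly within its interval, draws
n by inverse-CDF from the geometric law at the interval's true (r, ε)
(platform-stable given the seed), and re-observes ages in five datasets
with multiplicative lognormal noise (σ = 0.1), emulating between-study
calibration disagreement while keeping ages positive.  Defaults — 300
families, two intervals split at 66 My with (r, ε) = (0.03, 0.6) older and
(0.08, 0.6) younger, ages in (70, 140) and (15, 64) My — sit in the range
family-level fits typically infer for angiosperms, with the faster young
interval reflecting the usual acceleration toward the present.

Ground-truth outliers: 30% of families are forced species-poor (n = 1; real
depauperons are monotypic or nearly so) and 5% species-rich (n set to 20×
the largest true k_upper across that family's per-dataset ages), mirroring
the ~30%/5% composition observed for angiosperm families.  The 20×
exceedance represents the orders-of-magnitude gap real rich families show;
it also keeps ground truth decisively outside the classifier's
profile-widened bounds even though the outliers themselves contaminate the
interval fits (the pipeline fits on everything, as the source analyses do).
Trait tables draw per-family proportions from Beta distributions
(concentration 10) whose means shift ±effect between categories; zero
effect gives exchangeable null traits.  Occurrences are Gaussian clusters
on the globe labelled by a synthetic partition (eight 45° longitude
sectors, fourteen latitude bands), with duplicates and genus-only names
injected at configured rates to exercise cleaning.

What passing tests therefore show: the estimator, bounds, consensus logic,
and test battery behave correctly *when the model holds* and when
departures are of the injected kinds.  The generator does not emulate
phylogenetic non-independence among families, rate variation within
intervals, age-richness correlation induced by taxonomic practice, spatial
sampling bias, or real ecoregion geometry — conclusions about real data
rest on the method, not on these tests.

## Problem sizes and numerical choices

Tests and the acceptance script use the canonical r-grid with λ truncated
at 5/My and ~150–500 clades per fit; coverage checks use 10,000 geometric
draws; FDR checks use 20 null traits × 100 replicates at the 75/161/12
category sizes.  All randomness flows through `numpy.random.default_rng`
seeds; grid ties break toward small (r, λ); degenerate inputs (empty clade
sets, zero marginals, empty groups, non-ultrametric trees beyond a 1e−6
relative tip-spread tolerance) raise typed errors rather than silently
proceeding, except where a warning-and-skip is the documented contract
(missing ages, unlabeled records, small expected counts).

## Known limitations

- The ±1 log-unit profile region under-covers (see above); this is the
  method's published rule, kept as the default and exposed as a parameter.
- Clade-size bound coverage is nominal only for β near 1; for young/slow
  clades the geometric law's discreteness makes the real-valued bounds
  conservative at the bottom (monotypic families always classify low).
- Range classes approximate a continent-based definition with realm
  counts; with very large gap thresholds or wrap-around longitudes the
  bounding-window rule for highly_localized ignores antimeridian wrap.
- No phylogenetically corrected association tests are provided; the
  design is deliberately topology-free.
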