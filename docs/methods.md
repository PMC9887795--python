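# Methods

## Study design emulated by the simulator

The pipeline is built for cohorts of multiparous sows monitored by
ad-libitum electronic feeders through a lactation standardized to 28 days
(day 0 = farrowing). The default simulated cohort mirrors the reference
herd: 1,058 sow-cycles; parity classes 2 / 3–5 / 6+ in proportions
229:656:173; lactation length drawn from N(27.15, 1.13²) days, rounded and
truncated to [21, 28]; and five feed-intake patterns mixed at
38.5 / 24.0 / 18.4 / 15.2 / 3.9 %.

### Archetype curves

Each pattern's expected daily-feed-intake (DFI) curve has three regimes:

* **Days 0–6** — geometric rise at exactly the feeder-cap rate
  (1.20× per day). The electronic feeder limits each day's allowance to
  1.20 times the previous day's intake during early lactation, and appetite
  recovery after farrowing is assumed to track that ceiling, so the
  expected curve satisfies the cap with equality. This choice is also what
  makes the calibration self-consistent: a curve rising faster than the cap
  could never be realized by the simulator.
* **Days 7–21** — piecewise linear between knot levels at days 7, 14, 21
  (the cap is lifted from day 7, producing a small upward step).
* **Days 21+** — constant plateau.

The day-0 level and the three knots per pattern are the closed-form
solution of four linear equations equating the curve's expected feed totals
over days 0–6, 7–14, 15–21 and 22–27 with the calibrated period totals
(kg) of the five patterns (e.g. 25.5 / 61.3 / 61.2 / 57.0 for `1-HH` down
to 11.9 / 30.9 / 36.0 / 37.0 for `5-LL`). The fit is exact to machine
precision, the `5-LL` curve lies strictly below all others on every day,
and the reference `1-HH` curve is non-decreasing up to the plateau. The
`3-HM` and `4-MM` archetypes dip slightly between days 7 and 14 — that
mid-lactation decrease is the defining feature of an `HM`-type pattern,
not a fitting artifact.

### Noise model and defaults

| parameter | default | meaning |
|---|---|---|
| `day_noise_cv` | 0.08 | multiplicative lognormal day-to-day noise (mean 1) |
| `drop_event_rate` | 0.0 | per-sow-day probability of an intake-drop event |
| `drop_factor_range` | (0.2, 0.6) | multiplier applied on a drop day |
| `feeder_cap_factor` | 1.20 | day-over-day cap, enforced on days 1–6 |
| `invalid_sow_rate` | 0.02 | injected primiparous/short/nurse records |
| `born_alive_sd` | 3.0 | rounded-normal sd of litter counts |
| `wfsi_shape` | 2.0 | gamma shape of the weaning-to-service interval |

Daily intake is the archetype value times lognormal noise with the
configured coefficient of variation, optionally hit by drop events, then
capped at 1.20× the previous day's realized intake on days 1–6. With noise
and drops off, every trajectory equals its archetype exactly.

Reproductive outcomes are drawn per pattern from the calibrated
conditional means: born-alive as a rounded normal, stillborn and mummified
as Poisson (total born is their sum, which reproduces the reference-herd group
means within rounding), the weaned count as a binomial survival draw on a
post-fostering start litter implied by the weaned mean and preweaning
mortality, the weaning-to-first-service interval (WFSI) as a right-skewed
gamma (so interval-type outcomes exercise the nonparametric branch, as
they should), and the next-cycle farrowing outcome as Bernoulli with
next-cycle prolificacy drawn only for sows that farrow again.

**What the generator does not emulate.** Within-day meal events, nurse-sow
management, piglet-level cross-fostering flows, between-sow heterogeneity
*within* a pattern (every sow of a pattern shares one mean curve), serial
correlation of appetite across days, and repeated cycles of the same sow
(records are independent units). Consequently, recovery results on
synthetic cohorts demonstrate correctness of the pipeline, not expected
performance on field data, where pattern-internal heterogeneity makes
cluster boundaries far fuzzier.

**Noise defaults and identifiability.** A design study on n = 500 cohorts
showed that the five-pattern structure is cleanly identifiable up to
`day_noise_cv ≈ 0.08` (silhouette argmax at k = 5, adjusted Rand index
≥ 0.95), while drop events are qualitatively destructive: with even a 1 %
daily drop rate the optimal k-medoid partition itself (verified against
the cost of the true partition) begins to absorb the small 3.9 % `5-LL`
cluster and split the large `1-HH` cluster, and the drop-induced satellite
points push the silhouette argmax above 5. Subperiod-mean Euclidean
clustering is simply not robust to such outliers — the medoid objective
tolerates them better than means would, but the feature space does not.
The defaults therefore represent the drops-rare regime consistent with
ad-libitum electronic feeding, where major intake drops are infrequent;
the drop mechanism remains available (`drop_event_rate`) for studying
exactly this brittleness.

## Features and normalization

Subperiod means use inclusive day ranges restricted to observed days (a
25-day lactation contributes days 22–24 to the 22–28 d mean). Lactations
of exactly 21 days have an empty 22–28 d subperiod; the default policy
imputes it from the 15–21 d mean and flags the record (`imputed_m22_28`),
with an `"error"` mode to reject instead. Z-scoring uses the sample (n−1)
standard deviation and stores column means/sds for exact inversion; a
zero-variance column is fatal and named.

## PAM and selection of k

The build phase draws k distinct rows uniformly (seeded); the swap phase
evaluates every (medoid, non-medoid) exchange by its exact new cost and
applies the single best strictly-improving swap until none exists.
Best-improvement is the default because it makes runs order-independent
and reproducible; a greedy first-improvement variant is available. Ten
random restarts are the default — a single random start, as in the
textbook sketch, is fragile — and the lowest-cost restart wins, earlier
restart on ties. All other ties (nearest medoid, equal silhouette across
k) break toward the lowest index / smaller k. On every random instance
with n ≤ 8 and k ≤ 3 in the test suite, the implementation attains the
exhaustive-enumeration optimum over all C(n, k) medoid sets.

Silhouette widths define singleton clusters and exact a = b = 0 ties as
s(i) = 0. `select_k` scans k from 2 to 10 by default; a full sweep to
n − 1 is possible but adds nothing — mean silhouette degrades monotonically
well before k = 10 on all cohorts examined.

## Pattern taxonomy

Period totals use the inclusive table periods 0–6 / 7–14 / 15–21 / 22–28,
which partition the (truncated) lactation, so they sum to the whole-
lactation TFI exactly. Letters grade each cluster's mean TFI per period
(week 1 = days 0–6, rest = days 7–28) against the **reference cluster**
(highest mean whole-lactation TFI): High above 90 %, Low below 65 % of the
reference mean, Medium between, boundaries inclusive to Medium. This
percent-of-reference convention is the default because it is the only
reading of the taxonomy that reproduces the canonical letter pairs of all
five patterns from their calibration period totals — cohort-level 65th/90th
percentile thresholds cannot label a cluster containing ~38 % of sows "H",
since that cluster's mean necessarily sits below the cohort's 90th
percentile. The percentile convention (type-7 linear interpolation) is
nevertheless implemented and selectable (`convention="percentile"`) for
sensitivity analysis. With k ≠ 5 the names fall back to `P1-…` without
error; ties on mean TFI break by the higher week-1 mean.

## Statistical comparisons

* **Gate.** Normality is tested on the one-way residuals by
  Kolmogorov–Smirnov with the Lilliefors correction (parameters are
  estimated from the data; statsmodels' table-based p-values keep the gate
  deterministic). Homoscedasticity uses the median-centered
  (Brown–Forsythe) Levene test. Both must exceed α = 0.05 for the
  parametric branch; otherwise Kruskal–Wallis with tie correction.
* **Pooled SEM.** Tables report one pooled SEM, `sqrt(MSE / n_h)` with
  n_h the harmonic mean of group sizes.
* **Letter displays.** All pairwise comparisons (pooled-MSE t tests, or
  Mann–Whitney on the nonparametric branch) are unadjusted at α = 0.05 —
  a Bonferroni switch exists — and compressed by insert-and-absorb, so
  groups share a letter exactly when not significantly different.
* **Planned contrasts.** Contrasts compare unweighted means of group
  means, with the standard error from the pooled MSE and the percent
  difference relative to the unweighted mean of the reference set. The
  unweighted convention is deliberate: it is the only one consistent with
  the reference-herd worked examples (−8.9 % born alive and +23.2 % stillborn
  for `5-LL` versus the rest).
* **Degenerate inputs.** All-identical values yield p = 1 with a warning;
  groups with no bred sows are omitted from farrowing-rate tests; records
  with zero total born are skipped in derived percentages.
* p ∈ (0.05, 0.10] is flagged as a tendency.

Under a simulated 5-group global null (2,000 replicates), both branches'
type-I error sits within [0.04, 0.06] at α = 0.05; the acceptance script
recomputes this at every run.

## Problem sizes

The test suite simulates cohorts of 60–2,000 sows; the cluster-recovery
check uses n = 500 at the default noise, and the acceptance script runs
the full pipeline at the reference cohort size (1,058). PAM caches the
full distance matrix (n² doubles; ~9 MB at n = 1,058), and a complete
acceptance run takes well under a minute on one core.

## Known limitations

* Records are treated as independent sow-cycles; no cluster-robust or
  repeated-measures handling of sows contributing multiple cycles.
* No covariate adjustment (e.g., parity) in the outcome comparisons.
* The taxonomy letters apply to clusters, not individual sows; per-sow
  re-labeling independent of cluster membership is out of scope.
* Recovery guarantees degrade sharply if intake-drop outliers are added;
  see the noise-defaults discussion above.
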