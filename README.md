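# sowpatterns

Lactation feed-intake patterns of multiparous sows: discovery by k-medoids
clustering of daily-feed-intake trajectories, a two-letter pattern taxonomy,
and the association of patterns with reproductive performance.

## Who this is for

Swine scientists and farm-data analysts working with electronic-feeder
records of lactating sows. Modern hyperprolific sows often fail to eat
enough in lactation; the *shape* of the intake curve — not just the total —
predicts weaning performance and the next cycle's outcome. This package
implements a reproducible pipeline that turns long-format daily intake
records into named feed-intake patterns and quantifies their reproductive
consequences. Because commercial farm data are rarely shareable, it ships a
calibrated cohort simulator so the entire pipeline is testable end to end.

## The method

1. **Inclusion filters.** The record unit is the sow-cycle. Primiparous
   sows, nurse sows and lactations shorter than 21 days are excluded;
   lactations are truncated to 28 days (day 0 = farrowing).
2. **Features.** Each sow-cycle is summarized by six subperiod means of
   daily intake (kg/d) over days 0–3, 4–6, 7–10, 11–14, 15–21 and 22–28,
   then each column is z-scored, `(x − mean(x)) / sd(x)`.
3. **Clustering.** Partitioning Around Medoids (written from scratch) on
   Euclidean distances: k random medoids, then repeated best-improvement
   (medoid, point) swaps until the cost `Σᵢ d(xᵢ, medoid(i))` cannot
   decrease, with seeded restarts. The number of clusters is chosen by the
   mean silhouette width `s(i) = (b(i) − a(i)) / max(a(i), b(i))`.
4. **Taxonomy.** Clusters are ranked by mean whole-lactation total feed
   intake (TFI); the top cluster is the reference. Per period (week 1 =
   days 0–6; rest = days 7–28) a cluster is **H**igh above 90 %, **M**edium
   between 65 % and 90 %, and **L**ow below 65 % of the reference cluster's
   mean TFI, giving names `1-HH … 5-LL`.
5. **Association.** Per outcome (prolificacy, weaned piglets, preweaning
   mortality, weaning-to-first-service interval, next-cycle farrowing and
   prolificacy): a Kolmogorov–Smirnov (Lilliefors) + Levene gate chooses a
   one-way F test or Kruskal–Wallis; unadjusted pairwise tests are
   compressed to a compact letter display; planned contrasts compare
   pattern sets with percent differences relative to the unweighted mean of
   the reference set.

## Worked example

```bash
sowpatterns simulate --n-sows 150 --seed 5 --out runs/sim
sowpatterns analyze --intake runs/sim/intake.csv --repro runs/sim/repro.csv \
    --truth runs/sim/truth.csv --seed 5 --out runs/analysis
```

prints

```
k = 5; patterns: 1-HH, 2-MH, 3-HM, 4-MM, 5-LL
adjusted Rand index vs truth: 0.964
```

meaning the silhouette profile peaked at five clusters, the five clusters
map onto the canonical letter pairs in descending-TFI order, and the
partition agrees with the simulator's ground-truth pattern assignment at an
adjusted Rand index of 0.964 (1.0 would be perfect recovery).
`runs/analysis/` then contains the pattern summary (`pattern_table.csv`,
one row per pattern with counts, % of sows, period TFIs and mean daily
intake), the silhouette profile, per-pattern mean raw and normalized intake
curves, outcome comparison tables with SEM, p-values and letter displays,
farrowing rates with a chi-square homogeneity test, planned contrasts, and
`run_log.json` with the seed, config hash and exclusion counts.

The same pipeline is available as a library:

```python
from sowpatterns import (SimConfig, generate_cohort, apply_inclusion_filters,
                         feature_table, zscore_columns, select_k)
lacts, repro, truth = generate_cohort(SimConfig(n_sows=500, seed=42))
kept, _ = apply_inclusion_filters(lacts)
profile = select_k(zscore_columns(feature_table(kept)), seed=42)
print(profile.best_k)   # 5
```

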