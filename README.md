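# mealpatterns

Temporal clustering of protein and indispensable-amino-acid (IAA) intake
from timestamped food diaries.

## The problem

Protein adequacy is usually judged on daily totals, but muscle protein
synthesis responds to protein *per eating occasion* (EO): roughly 20 g per
meal, or 0.24 g per kg body weight, is the lowest threshold with a
demonstrated anabolic response. Diets that meet the daily Estimated Average
Requirement can still deliver most EOs below that per-meal threshold —
a particular concern in vegan cohorts, where protein density and amino-acid
digestibility are lower. This package implements a data-driven analysis of
*when and how much* protein people eat:

1. **Eating occasions.** Diary records sharing one timestamp form an EO.
   Per-item protein is computed from a food-composition table, amino-acid
   profiles (mg AA per g protein) are scaled to each food's protein
   content, and everything is adjusted by true-ileal-digestibility (TID)
   coefficients. Items under 0.5 g of protein are dropped; any
   participant-day with a missing clock time is excluded in full.
2. **Time series.** Each retained participant-day ("individual.day")
   becomes an ordered series of per-EO utilisable protein values.
3. **Dynamic Time Warping.** Series are compared with DTW under the
   symmetric step pattern (diagonal weight 2), normalized by the summed
   series lengths `n + m` so days with different EO counts are comparable:
   `d_norm(x, y) = D(n, m) / (n + m)` with
   `D(i,j) = min(D(i-1,j-1) + 2|x_i - y_j|, D(i-1,j) + |x_i - y_j|, D(i,j-1) + |x_i - y_j|)`.
4. **Clustering and embedding.** Ward.D2 agglomerative clustering over the
   DTW dissimilarity matrix (Lance–Williams update on squared
   dissimilarities), cut at *k* = 3, with an average-silhouette scan over
   candidate *k* and a classical MDS projection with per-dimension
   variance fractions.
5. **Adequacy statistics.** Per-cluster means, percentage of EOs below the
   20 g and 0.24 g/kg thresholds, daily intake versus the sex-specific EAR
   (0.68 / 0.60 g/kg/day), food-group contributions to protein and each
   IAA, 24-hour intake profiles, and Kruskal–Wallis + Dunn (Bonferroni)
   tests across clusters.

Because raw dietary data of this kind are rarely shareable, the package
ships a synthetic-cohort generator whose three meal-pattern archetypes
(frequent low-protein "grazing", moderate, infrequent high-protein) are
first-class, tested code — every downstream stage is exercised end to end
without external data.

## Worked example

```python
import numpy as np
import mealpatterns as mp

# a 193-individual, 4-day cohort with 6 days of unusable time records
config = mp.CohortConfig(n_individuals=193, n_days=4, n_corrupted_days=6, seed=1)
participants, diary, truth = mp.generate_cohort(config)

clean, excluded = mp.validate_days(diary)          # drops the 6 corrupted days
eos, items = mp.build_eos(clean, mp.default_composition())
series = mp.to_series(eos)
print(len(series))                                 # 766

dm = mp.distance_matrix(series)                    # normalized DTW, 766 x 766
model = mp.WardClustering(n_clusters=3).fit(dm)
labels = mp.renumber_by_value(
    model.labels_, np.array([s.values.mean() for s in series])
)

report = mp.cluster_summary(
    {s.series_id: int(l) for s, l in zip(series, labels)}, eos, participants
)
print(report.summary[["cluster", "mean_protein_g_per_eo",
                      "mean_eos_per_day", "pct_eos_below_relative"]])
```

Output:

```
766
   cluster  mean_protein_g_per_eo  mean_eos_per_day  pct_eos_below_relative
0        1               6.463086          6.673846               99.815583
1        2              11.344650          5.133333               93.034238
2        3              18.957479          5.036036               37.388193
```

Cluster 1 is the grazing pattern — about 6.7 EOs per day at 6.5 g protein
each, with essentially every EO under the 0.24 g/kg threshold. Cluster 3
eats less often (5.0 EOs/day) but at 19 g per EO; still, over a third of
its EOs miss the relative threshold. The same structure drives the
silhouette scan (the two low-protein clusters merge readily, so *k* = 2
maximises mean width while *k* = 3 separates the moderate and high
patterns) and the MDS projection, where dimension 1 carries most of the
variance and orders clusters by intake level.

A command-line interface wraps the same pipeline:

```bash
mealpatterns simulate --out cohort/ --seed 1
mealpatterns run --diary cohort/diary.csv --composition cohort/composition.csv \
    --participants cohort/participants.csv --out results/ --k 3
mealpatterns scan-k --diary cohort/diary.csv --composition cohort/composition.csv \
    --participants cohort/participants.csv
```

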