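# Methods

## Overview

The package turns timestamped food-diary records into per-eating-occasion
(EO) series of utilisable protein, clusters the series by temporal shape,
and summarises protein adequacy per cluster. This note records the model,
the parameters that matter, what the synthetic cohort does and does not
emulate, and the numerical choices made where the design was open.

## Protein-quality arithmetic

A food's amino-acid profile is stored per gram of protein (mg AA / g
protein), the form in which reference profiles are published. The
amino-acid content of a portion is therefore `profile x portion protein`,
converted mg to g; this makes normalising a reference profile to a
locally reported protein content a single multiply. True ileal
digestibility (TID) is applied componentwise: the per-food protein TID to
total protein and each amino acid's own TID to that amino acid. A TID
value must exist for every nonzero component — silent pass-through would
overstate utilisable intake. The tracked set is the seven amino acids
with plant-food TID coverage: tryptophan, threonine, leucine, lysine,
methionine, cystine (carried although not strictly indispensable, since
it is digestibility-adjusted the same way) and histidine.

Whether the per-meal protein threshold literature intends adjusted or
unadjusted protein is immaterial here because the whole pipeline reports
on the utilisable (adjusted) scale; the one place the scale matters is
the item filter, below.

## Eating occasions and series

An EO is the set of records sharing one exact (participant, date, time)
stamp — EO identity is the timestamp, with no proximity window, so two
records a minute apart are two EOs. Items under 0.5 g protein are
dropped before summation (strict `<`), evaluated on
digestibility-**unadjusted** protein; the alternative (post-TID) is a
config switch (`filter_after_tid`), since the convention is genuinely
ambiguous — the difference touches only items within ~20% of the 0.5 g
boundary. A day containing any record with a missing clock time is
excluded in full: clock times define EOs, so a partially timed day
cannot be aggregated honestly. Callers with externally imputed times can
repair the frame before `validate_days`. Days are numbered 1-based per
participant in date order; calendar gaps do not renumber. Days are
00:00–23:59 windows; an EO at 00:30 belongs to its calendar date.

The filter's effect is tracked by a coverage report: the cohort-level
fraction of (unadjusted) protein retained and the per-participant
minimum, both of which should remain high (>98% / >92%-style) if the
filter is only removing trivial items.

## Dynamic time warping

Series are compared on per-EO protein values only — clock times are
deliberately not inputs, so the alignment compares intake *shape*
(sequence and magnitude of EOs), not timing. Local cost is `|x_i - y_j|`;
the step pattern is the classic symmetric one with diagonal weight 2,
whose total path weight for an (n, m) alignment is n + m regardless of
the path, making `D(n,m)/(n+m)` a length-comparable normalized distance —
the only standard normalizable default, and the one adopted here. No
warping window is applied. Values are raw grams, not z-normalized:
standardising would erase exactly the intake-level differences the
clusters are meant to capture. DTW violates the triangle inequality;
nothing downstream assumes it is a metric.

Tie-breaks among predecessor cells (diagonal > up > left) affect only the
reported warping path, never the distance. The full pairwise matrix is
computed with a batch-vectorised dynamic programme (pairs grouped by
length pair), so the 766 x 766 matrix takes well under a minute on one
CPU.

## Ward.D2 clustering

Agglomeration uses the Lance–Williams update on *squared*
dissimilarities,

    d(k, i∪j)^2 = [(n_i+n_k) d(k,i)^2 + (n_j+n_k) d(k,j)^2 − n_k d(i,j)^2] / (n_i+n_j+n_k),

recording the unsquared merge height (the Ward.D2 variant). Each step
merges the globally closest pair; since Ward is reducible this yields
monotone non-decreasing heights, asserted in tests. Merge ties break on
the lexicographically smallest index pair. On DTW input Ward is a
heuristic (the dissimilarities are not Euclidean, so "variance" is
nominal); this is documented behaviour, not corrected. Cutting the tree
undoes the last k−1 merges, giving partitions that are nested across k.
Cluster numbers are then made semantic by `renumber_by_value`: cluster 1
is the lowest mean-protein pattern, ties broken by size.

Model selection is guided by the average silhouette width
`s(i) = (b(i) − a(i)) / max(a(i), b(i))` (singletons score 0) scanned
over k; domain judgement may override the argmax — with the default
cohort the scan prefers k = 2 (the two lower-protein patterns merge
readily) while k = 3 separates the moderate from the high pattern, and
both diagnostics are reported.

## Classical MDS

Torgerson scaling: double-centre the squared-distance matrix,
`B = −(1/2) J D² J`, eigendecompose, coordinates are the top
eigenvectors scaled by √λ. Negative eigenvalues — expected for
non-Euclidean DTW input — are excluded from both the coordinates and the
variance denominator, so `variance_fraction_i = λ_i / Σ λ_positive`.
If fewer positive eigenvalues than requested dimensions exist, the
embedding shrinks with a warning. On exactly Euclidean input the
full-rank embedding reproduces the distances to numerical tolerance
(asserted to 1e-8 in tests).

## Adequacy statistics

Per-EO thresholds are the lowest values the per-meal literature
supports — 20 g absolute and 0.24 g/kg body weight — with "below"
always a strict `<` (matching the strict "less than 0.5 g" item-filter
convention). Per-cluster means are EO-weighted (each EO counts once);
threshold percentages are over all EOs pooled within a cluster. A
secondary individual-level metric (share of individuals whose *mean* EO
protein is below threshold) is reported at cohort level, because both
denominators are in common use and they can differ sharply. Daily
totals per individual.day are compared to the sex-specific EAR (0.68 g/kg/d
male, 0.60 female). Total IAA per EO sums the seven tracked amino acids.

Food-group contributions are percentages of each cluster's total for
protein and each IAA; groups under 5% of the cluster's *protein* fold
into "Others" for all nutrients, keeping the grouping consistent across
panels. Hourly profiles are mean per-EO intake in 24 bins (bin h covers
[h:00, h+1:00)); empty bins are reported as missing, not zero.

Kruskal–Wallis uses the tie-corrected H with a chi-square reference
(g − 1 df); when every observation is identical the tie correction is
zero and the result is flagged degenerate rather than fabricated. Dunn's
post hoc z uses joint ranks with the tie-corrected variance, two-sided
normal p-values, Bonferroni multiplied by the number of pairs and capped
at 1. For clusters, each individual is attributed to their modal cluster
for body-composition comparisons (individual.days may straddle clusters).

## Synthetic cohort

The generator emulates a 193-individual, 4-day diary cohort with three
latent archetypes, each assigned per individual:

| archetype | mix | EOs/day | protein/EO (g) | sd (g) | window | body fat % |
|---|---|---|---|---|---|---|
| grazing | 0.384 | 6.5 | 6.5 | 1.8 | 07–22 | 32.0 (6.5) |
| moderate | 0.460 | 5.2 | 11.4 | 2.4 | 07–21 | 30.0 (7.6) |
| infrequent_high | 0.156 | 5.0 | 19.0 | 3.0 | 08–21 | 25.4 (6.8) |

EO counts are `1 + Poisson(mean − 1)` (minimum one EO, exact mean).
Per-EO protein targets are truncated-at-zero normal draws on the
**utilisable** scale — item amounts are back-computed through each
food's protein TID so the analysis-side cluster means land on the
calibration targets. The within-archetype standard deviations are free
parameters (no published within-cluster spread exists to copy); they
were chosen once as plausible day-to-day meal variability that keeps
neighbouring archetypes overlapping rather than trivially separable.
Each EO is realised as 1–3 items drawn from archetype-specific
food-group weights over a compact 15-food plant-food table, with a
0.6 g per-item protein floor so the 0.5 g filter only bites on
explicitly injected trivia (`low_protein_item_rate`, default 0, set to
0.15 in the acceptance script to exercise the filter at roughly the
sub-1% protein share a real diary shows). Timestamps are distinct
minutes sorted within the archetype's eating window, so the timestamp
grouping rule reconstructs EO identity exactly. Body weights are
sex-specific normals (73% female cohort); body-fat means differ by
archetype so the cross-cluster body-composition tests have signal; BMI
does not differ by design.

What the generator does **not** emulate: energy and non-protein
nutrients, weekday/weekend structure, within-individual day-to-day
archetype switching, correlated food choices across EOs, supplement
timing, or misreporting. Passing tests therefore demonstrate that the
pipeline recovers planted temporal-protein structure, not that any
particular real cohort has three clusters.

## Problem sizes and determinism

The default analysis scale is the full 766-series cohort; the pairwise
DTW matrix, Ward tree, silhouette scan and MDS for it run in seconds,
and the multi-seed recovery test repeats the complete pipeline across
ten seeds. Unit tests use smaller cohorts (18–40 individuals) where the
full scale adds nothing. Every stochastic step flows from a single
`numpy.random.default_rng(seed)` stream; identical (config, seed) gives
byte-identical diaries and checksum-identical pipeline artifacts. The
`--threads` CLI flag is accepted for interface compatibility; the
pairwise computation is batch-vectorised on one worker and results are
invariant to the flag by construction.

## Known limitations

- Ward on DTW dissimilarities has no variance-decomposition guarantee;
  cluster shapes are interpretable only through the summaries.
- The silhouette criterion inherits the same caveat and, with
  overlapping intake distributions, genuinely prefers k = 2; choosing
  k = 3 is a domain call the package surfaces but does not make.
- The 0.5 g item filter convention (pre- vs post-TID) is configurable
  because the field convention is ambiguous; defaults use pre-TID.
- Classical MDS discards negative-eigenvalue structure; the reported
  variance fractions describe the positive part of the spectrum only.
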