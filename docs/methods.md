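# Methods

## The subtyping procedure

The pipeline treats subtype discovery as a two-stage problem: an
*unsupervised* stage that proposes patient partitions from expression
alone, and a *supervised* stage that asks which proposed cluster is
associated with the binary post-surgical outcome (1 = seizure recurrence,
0 = seizure freedom at ≥ 1 year).

**Clustering grid.** Sample–sample distances are computed on the scaled
matrix with Manhattan, Canberra (classic |xᵢ|+|yᵢ| denominator, 0/0 terms
omitted; the signed-sum |xᵢ+yᵢ| variant is available by flag), Minkowski
(power 2 by default, configurable) and Euclidean metrics. The binary
distance (mismatch fraction over positions where either value is nonzero)
is implemented and selectable but excluded from the default grid: on
scaled, centred data no value is exactly zero, every pairwise distance
collapses to 0, and the resulting dendrogram is an artifact of
tie-breaking that can fluke an outcome association. The default search is
therefore 4 metrics × 3 linkages = 12 configurations.

**Linkage.** Agglomeration is a hand-written Lance–Williams loop because
the two Ward conventions must both be available: *Ward D* applies the
Ward update to the supplied distances as-is; *Ward D2* applies it to
squared distances and reports square-root heights; *complete* takes
pairwise maxima. Ties in the minimum working distance break on the
smallest (left, right) node-id pair, making every tree deterministic. The
implementation is validated against frozen reference output from an
independent R `hclust` run, against `scipy.cluster.hierarchy` for
complete/Ward-D2, and against a brute-force re-computation oracle on
small instances.

**Association and stopping.** At each cut k (labels assigned 1..k by
first appearance in leaf order) every cluster is compared to the rest by
maximum-likelihood logistic regression of outcome on the membership
indicator plus sex, pathology dummies (reference: hippocampal sclerosis,
the most frequent category), surgical side and epilepsy duration;
covariates constant in the analysed subcohort are dropped as
unidentifiable. The Wald two-sided p for the indicator is BH-adjusted
across the k clusters of that cut. Phase 1 raises k from 2 until some
cluster clears FDR < 0.2 (an exploratory threshold) or k = 10. Phase 2
keeps splitting while the minimum nominal p over clusters still improves
and stops just before it degrades. Across the grid, the call whose best
cluster has the lowest FDR wins; ties fall to smaller k, then grid order.

**Separation.** With ~40 subjects and small clusters, perfectly separated
fits happen. Fits are done with IRLS (statsmodels GLM/binomial), which
returns the diverged estimate rather than raising; a fit is flagged
`separation_flag` when any fitted probability is within 1e-8 of 0/1 or a
coefficient passes ±15, and is reported as produced with
`converged=False`. A Firth (Jeffreys-penalised) refit is available behind
a flag for users who prefer finite estimates; the default reports the
unpenalised fit because the search criterion (minimum FDR) should see the
same p-values a standard analysis environment would produce. Degenerate
association p-values (failed fits) are treated as 1.0 in stopping
comparisons.

**Phase-2 comparisons** use the minimum nominal p over *all* clusters at
each cut (not only significant ones), and BH runs within each cut, not
across cuts — with k hypotheses at cut k, adjusting within the cut is the
reading consistent with testing "the k cluster associations" as a family.

## Downstream statistics

**Bootstrap CIs.** The recurrence proportion in a flagged cluster gets a
percentile bootstrap CI: resample the cluster's outcome vector with
replacement 1000 times and take the empirical 2.5/97.5 percentiles
(linear-interpolation quantile). The percentile method was chosen over
BCa for transparency; at these cluster sizes the bounds agree with exact
binomial quantiles of the plug-in distribution, which the tests verify
independently. The companion "bootstrap t-test" — a two-sample t between
the two bootstrap proportion distributions — is implemented as specified
but is anti-conservative by construction (its t statistic grows with
√n_boot); the tests document this artefact and the result carries a
defined/undefined flag for zero-variance cases.

**Overlap.** Cross-modality cluster overlap uses the hypergeometric upper
tail (one-sided Fisher) with the universe set to the samples measured in
both modalities, and reports 100·|A∩B|/|A∪B| (Jaccard) as the display
percentage.

**Differential expression.** Pooled-variance Student t per feature
(Welch behind a flag), BH across retained features, and a shifted log2
fold change: each feature's values (both groups jointly) are translated
so the minimum becomes ε = 0.001, then the ratio of group means is
logged. The shift uses the *per-feature* minimum; a global-matrix-minimum
variant would change magnitudes but not signs. Zero-variance comparisons
return t = 0, p = 1 rather than NaN.

**Preranked GSEA.** Features are ranked by the shifted log2 FC
(descending; ties break on feature id for determinism). Hits add
|stat|^w / Σ_set |stat|^w (w = 1), misses subtract 1/(N − |set|); the
score is the running sum's largest excursion, sign retained. The null
permutes gene labels (random same-size sets); the nominal p is the
fraction of same-sign null scores at least as extreme, floored at
1/n_perm; NES divides the score by the mean magnitude of same-sign null
scores; BH runs across the tested sets. This simple permutation estimator
will not reproduce the very small FDRs adaptive multilevel estimators can
report; it is calibrated (null p-values are uniform in the tests) but has
resolution 1/n_perm.

**Upstream regulators.** The activation z-score is the unweighted form
(n_consistent − n_inconsistent)/√n_total over a regulator's
DE-significant targets, with a repression edge expecting the target DOWN
under an active regulator. |z| ≥ 2 calls activated/deactivated.
Literature-confidence edge weights (as in proprietary knowledge-base
tools) are out of scope, so z magnitudes are comparable only within this
package. Concordance compares a deactivated (activated) call with
observed significant down- (up-) regulation of the regulator itself;
regulators that are unmeasured, not significantly changed, or
indeterminate (|z| < 2) count as untestable, and the headline concordance
rate is concordant/(concordant + discordant). With the default network
density of 5 expected targets per regulator, roughly a quarter of planted
regulators draw fewer than 4 targets and can never reach |z| ≥ 2 — an
arithmetic property of the unweighted score, not a failure of recovery.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes,
with defaults shaped like the study cohort it stands in for:

| parameter | default | rationale |
|---|---|---|
| n_subjects | 40 | cohort size; 23 recurrences expected |
| availability | 40/35/32/30 | blood miRNA all; blood mRNA 35; brain assays 32, of which 30 inside the blood-mRNA subset (the "all four assays" core) |
| subtype_fraction | 0.575 | 23 of 40 subjects, the flagged risk cluster's size |
| recurrence rates | 0.80 / 0.40 | inside vs outside the planted subtype |
| n_features | 400 miRNA / 2000 mRNA | scaled down ~5× from quantified feature counts for desk-scale runs |
| n_signal_features | 25% of features | planted signal fraction |
| effect_size | 1.5 | shift in within-batch SD units; miRNA signal down, mRNA signal up |
| coupling_fraction | 0.5 | share of brain signal features shared with the blood signal (same ids) |
| n_batches | 2 | exercises within-batch centring |
| batch effect | N(0, 0.5) per feature×batch | additive offset |
| network_density | 5 | expected Poisson targets per regulator; decoy edges among non-signal features at the same density, random sign |

Expression is a per-feature log-normal(μ=4, σ=1) baseline plus the batch
offset plus unit-normal noise, so `effect_size` is in within-batch SD
units. Covariates (sex, side, pathology frequencies, duration) are drawn
independently of subtype membership at frequencies matching the cohort
table, which isolates the cluster→outcome signal for recovery tests; a
confounded mode is not provided. What the generator does *not* model:
RNA-seq count noise (negative-binomial mean–variance coupling, library
size), feature–feature correlation beyond the planted block, isoform
structure. Passing recovery tests therefore shows the procedure works
when its distributional assumptions hold at the planted effect size — not
that real cohorts carry such signal.

## Recovery behaviour and known limitations

- At the default conditions (12-configuration grid, 23/40 subtype,
  effect 1.5 SD) the full preprocess → grid-subtyping path recovers the
  planted subtype with ARI ≥ 0.7 in ~85% of replicates. Raising the
  effect does not monotonically help: with very clean separation the
  k = 3 cut splits the true cluster and a sub-cluster can win on FDR —
  the selection rule is exploratory by design and inherits this
  instability.
- Under a global null (no planted effect, equal recurrence rates) the
  fixed-cut k = 3 minimum nominal p is not anti-conservative
  (P(min p < 0.01) ≤ 0.05 over 200 replicates), but the *selected-best*
  call across a grid and over cuts is an optimised statistic; its FDR
  values are exploratory, not family-wise guarantees.
- The near-zero-variance filter compares values after rounding to 8
  significant digits; on continuous scaled data it removes only
  (near-)constant features, which is its intended role — it bites on
  zero-inflated count-derived data.
- Problem sizes in the tests (feature counts, replicate counts,
  permutation counts) are scaled to desk scale; all are package-level
  choices and configurable upward.
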