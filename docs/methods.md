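# Methods

## Problem and model

The package builds a screening instrument for dysbiosis risk, defined as
low gut-microbiota richness. The pipeline has four statistical layers:

**Richness estimation.** Per-sample alpha diversity from an ASV count
table. Chao1 defaults to the bias-corrected estimator
`S_obs + F1(F1−1)/(2(F2+1))` (the form vegan computes); the classic
`S_obs + F1²/(2F2)` sits behind a flag and itself falls back to the
bias-corrected form when no doubletons exist. An all-zero sample has, by
convention, richness 0; richness estimators refuse non-integer input since
they are undefined on relative abundances. Shannon entropy is reported in
nats and Simpson as the complement `1 − Σp²`.

**Outcome construction.** The binary at-risk outcome is *richness strictly
below the healthy reference group's q-quantile* (default q = 0.25).
Quantiles use linear interpolation (type 7, `h = (n−1)q + 1`) so cutoffs
are reproducible against the common statistical defaults; the method is
recorded in the outcome definition. Ties at the cutoff are negative.
Because the direction of conditioning ("condition of interest" = diseased
or = healthy) changes which group's misclassification is called
sensitivity, the quantile scan always reports both conventions with their
Youden J.

**Score optimization.** The instrument is the additive integer score
`s_i = Σ_j w_j x_ij` over binary exposure items, `w_j ∈ {0,…,4}`. The
default objective is the AUC of the score against the outcome — threshold-
free and matching the eventual ROC validation; Youden-at-best-cutoff is an
alternative. With at most 7 informative items the 5^k grid is enumerated
exactly; beyond that, seeded coordinate ascent runs from 25 random integer
starts, sweeping the items in a freshly randomized cyclic order each sweep
and accepting only strict objective improvements until a full sweep makes
no change. After convergence a deterministic parsimony pass lowers any
weight whose reduction leaves the objective unchanged. Everywhere, ties
break identically: higher objective, then smaller total weight, then the
lexicographically smaller weight vector — results are bitwise reproducible
for a fixed seed. Items with constant responses cannot affect a ranking
objective and are pre-assigned weight 0 (flagged as degenerate). The random
sweep order and the post-hoc (rather than in-sweep) parsimony matter: with
a fixed order and equal-objective shrink moves during the ascent, the
search demonstrably strands in local optima that the randomized variant
escapes at the same restart budget. Zero-weight items are then eliminated,
and the integer cutoff maximizing Youden's J under *positive iff score > t*
is selected (ties toward higher specificity, then smaller t). No
cross-validation is applied by default; the construction is deliberately
in-sample, so reported training metrics are optimistic.

**Validation.** Sensitivity, specificity, PPV and NPV come from the
confusion matrix; zero-denominator ratios are NaN with an explicit flag,
never 0. The AUC is the tie-corrected rank statistic
`[#(pos>neg) + ½#(pos=neg)]/(n₁n₀)`; the ROC curve is emitted under both
`>` and `≥` threshold conventions and its trapezoidal area equals the rank
statistic to numerical precision. The 95% CI uses the DeLong variance from
midrank structural components (implemented here; no installed package
exposes it), and the "AUC ≠ 0.5" p-value is the corresponding normal test.
Pearson correlations carry Fisher-z intervals `tanh(z ± z₀.₉₇₅/√(n−3))`.
Group comparisons of binary items use the uncorrected Pearson chi-square on
the 2×2 table: the reference cohort's published three-decimal p-values
(0.009 for antibiotic use, 0.011 for altered bowel habit) are reproduced
only by the uncorrected statistic, so the Yates correction is opt-in.

**Beta diversity.** Jensen–Shannon divergence (natural log, bounded by
ln 2) on ASV-level relative abundances; the square-root metric variant and
the aggregation level are configurable, and the choice is recorded in the
output metadata. PERMANOVA partitions the Gower sums of squares
(`SS_total = Σ_{i<j} d²_ij / n`, within-group terms divided by group size)
into a pseudo-F with `R² = SS_between/SS_total`, and permutes labels with a
seeded generator, `p = (b+1)/(m+1)`, m = 999 by default. Benjamini–Hochberg
adjustment is applied across whatever battery of hypotheses a run tests.
The dispersion test embeds samples by classical PCoA (all positive axes),
takes each sample's distance to its group centroid, and permutes the
one-way ANOVA F on those distances; distances to own-group centroids are
exchangeable under the null only for comparable group sizes, so the null-
calibration suite uses balanced groups. PCoA reports negative eigenvalues
rather than dropping them and truncates (with a warning) when more axes are
requested than positive eigenvalues exist.

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes: two
groups (defaults 167 patients, 52 healthy controls) answer the canonical
15-item registry with independent Bernoulli responses at group-specific
prevalences taken from the published reference-cohort counts bundled in
`dysrisk.registry`. A latent liability `L_i = Σ_j w*_j x_ij + ε_i`
(planted integer weights, ε ~ N(0, 1.5 score units)) drives true richness
`S_i = max(10, 260 − 8·L_i + η_i)` with η ~ N(0, 15 Chao1 units). The
intercept/slope/noise calibration places the healthy group's 25th Chao1
percentile in the low 200s — the regime in which a quartile cutoff on
richness is scientifically meaningful — and gives score-richness
correlations around −0.6. The liability noise is kept in score units
(SD 1.5); since it enters richness multiplied by the slope, an SD
comparable to the richness noise would swamp the planted signal entirely
and push the reference quartile far below the intended regime. The floor
of 10 prevents non-physical richness. Default planted weights (4,3,2,2,1,1)
sit on six exposure items; the "ongoing treatment" item has prevalence 1.0
in both reference groups and is therefore constant in simulation — the
optimizer flags it degenerate.

Count tables draw, per subject, `S_i` taxa from a 400-taxon pool, give them
Dirichlet(0.5) relative abundances and multinomial reads at depth 20,000.
Pool taxa carry a fixed phylum taxonomy over eight phyla with a 2%
deliberately unclassified share, so phylum summaries and the F/B ratio are
exercised. At this depth the bias-corrected Chao1 tracks the planted
richness with Spearman ≈ 0.99 and median relative error under 10%.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: phylogenetic correlation between taxa,
compositional zero inflation beyond the multinomial, item-item dependence
(comorbid exposures co-occur in reality), recall bias in questionnaire
answers, and any group difference in community *structure* (the planted
effect is purely on richness). All randomness flows from one seeded
generator per operation: the same seed reproduces cohorts, counts and truth
bitwise.

## Numerical choices and problem sizes

Permutation p-values use the add-one estimator with m = 999 by default
(m = 99 in calibration suites, which run 200 replicates per test).
Optimizer objective comparisons treat differences below 1e-12 as ties.
The test suite's heavier simulations use 20 seeded replicates at cohort
size 300 (the 167:52 ratio scaled) for recovery checks, 50 seeded
instances at n = 60 for the heuristic-vs-exhaustive oracle, and n = 100
samples for richness-tracking — sizes chosen so the full suite completes
in well under a minute of simulation time while keeping Monte-Carlo noise
far from the asserted margins.

## Known limitations

- In-sample optimization overfits by design (mirroring the original
  construction): on default recovery cohorts the optimizer assigns a
  spurious positive weight to a truly null item in roughly a fifth of
  item-replicate cases, concentrated on rare exposures (prevalence < 6%),
  and the training AUC exceeds the planted-weight AUC by up to ~0.03. An
  optional k-fold evaluation exists but is off by default.
- The dispersion test's permutation scheme fixes the centroid distances
  computed from the observed grouping; with strongly unbalanced groups its
  null distribution is only approximately exchangeable.
- DYS/FQM-style external instruments are supported only as supplied numeric
  score columns evaluated through `evaluate_screening`; their internal item
  scoring is out of scope.
- Rarefaction/coverage normalization and phylogenetic beta-diversity
  metrics (UniFrac) are out of scope.
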