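# dysrisk

Construction and validation of questionnaire-based screening scores for
**dysbiosis risk**, operationalized as low gut-microbiota richness.

Clinicians need cheap triage tools that flag patients whose gut microbiota
is likely depleted before ordering 16S sequencing. `dysrisk` implements the
full statistical pipeline behind such a tool: starting from an ASV count
table, sample metadata (chronic-disease patients vs healthy controls) and a
15-item yes/no exposure questionnaire, it

1. computes **alpha diversity** per sample — Chao1 richness
   (bias-corrected, `S_obs + F1(F1−1)/(2(F2+1))`), Shannon entropy (nats)
   and Simpson's `1 − Σp²` — plus phylum-level relative abundances and the
   Firmicutes/Bacteroidetes ratio;
2. computes **beta diversity** — pairwise Jensen–Shannon divergence
   `JSD(P,Q) = ½KL(P‖M) + ½KL(Q‖M)` with `M = (P+Q)/2` — and tests group
   structure with one-factor **PERMANOVA** (pseudo-F, label permutation,
   `p = (b+1)/(m+1)`), a betadisper-style dispersion-homogeneity test, and
   classical PCoA;
3. defines the binary **outcome**: a subject is at risk when richness falls
   strictly below a quantile (default the 25th percentile, type-7) of the
   healthy reference group;
4. **optimizes integer item weights** `w_j ∈ {0,…,4}` of the additive score
   `s_i = Σ_j w_j x_ij` to maximize the AUC against that outcome —
   exhaustively for ≤ 7 informative items, otherwise by seeded multi-restart
   coordinate ascent — eliminates zero-weight items, and selects the integer
   score cutoff by Youden's J under the strict rule *positive iff score > t*;
5. **validates** the instrument: sensitivity/specificity/PPV/NPV, ROC AUC
   with DeLong 95% CI, Pearson correlation between score and richness with
   Fisher-z CI, simple linear fits, and uncorrected 2×2 chi-square tests for
   group comparisons of the items.

Because cohort-level microbiome data of this kind are rarely deposited, the
package ships a **synthetic cohort generator** (`dysrisk.simulate`) with
planted ground truth: group-specific item prevalences taken from a published
219-subject reference cohort, a latent liability that is linear in planted
integer weights, richness anti-correlated with liability, and
Dirichlet-multinomial ASV count tables whose estimated Chao1 tracks the true
richness. Every pipeline stage is tested against it.

## Worked example

One command simulates a cohort at the default study conditions
(167 patients / 52 controls) and runs every stage:

```bash
$ dysrisk pipeline --seed 7 --outdir demo/
richness cutoff 194.75; 7 items, score cutoff 6; sens 0.83 spec 0.79 AUC 0.881
```

Reading the output: the healthy group's 25th Chao1 percentile is 194.75, so
subjects with estimated richness below it count as at-risk; the optimizer
kept 7 of 15 items with positive integer weights (`demo/model.json`, e.g.
cesarean birth 4, short breastfeeding 3, smoking 3, …); a total score above
6 flags a subject, which on this cohort recovers the planted low-richness
subjects with sensitivity 0.83, specificity 0.79 and AUC 0.881
(`demo/report.json` carries the full confusion counts, DeLong interval and
score-richness correlation).

The same stages are available individually (`dysrisk simulate / alpha /
beta / outcome / build / evaluate`) and as library functions:

```python
import dysrisk as dr

meta, resp, richness, truth = dr.simulate_cohort(seed=7)
outcome, definition = dr.define_outcome(
    richness, groups=meta.to_frame().set_index("sample_id")["group"], q=0.25
)
model, trace, table = dr.build_model(resp, outcome.to_numpy(),
                                     outcome_definition=definition)
```

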