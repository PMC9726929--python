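# Methods

`cytodose` implements a dose-reconstruction analysis for radiation
biodosimetry that combines two automated cytogenetic assays — the
dicentric chromosome assay (DCA) and the cytokinesis-block micronucleus
assay (CBMN) — in a single machine-learning regression of absorbed dose.
This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohort generator does and
does not emulate, and the numerical choices that matter for
reproducibility.

## 1. Data model

One row is one blood-aliquot measurement:

| field | meaning |
|---|---|
| `age`, `sex`, `race`, `ethnicity` | donor demographics; sex 0 = male, race/ethnicity coded categoricals with 0 = unreported |
| `dose_gy` | nominal absorbed dose (Gy), the regression target |
| `dose_rate_category` | ordinal 0–4, from ~0.08 Gy/day up to single-pulse delivery |
| `mc_count`, `dic_count` | monocentric chromosomes scored and dicentrics found (DCA) |
| `bn_count`, `mn_count`, `mono_count` | binucleated cells scored, micronuclei found, mononucleated cells (CBMN) |

Derived indices: the dicentric **yield** = `dic/MC`; the raw micronucleus
index **Mi_BN** = `Mi/BN`; and the linearized index

    Mi_BN_c = Mi/BN + (1/k) * MN/BN

where the MN/BN term compensates the high-dose *turnover* of Mi_BN (at
high dose cell-cycle arrest removes scorable binucleated cells, so the
micronucleus index declines even though damage rises, while the
mononucleated fraction climbs).  `k` is a dimensionless calibration
constant chosen so the median of Mi_BN_c is linear in dose (section 3).

Aliquots with fewer than 20 binucleated cells **or** fewer than 20
monocentric chromosomes are removed before analysis; exactly 20 is
retained.  Filtering is idempotent and logged row by row.

## 2. Median dose–response model

Assay indices are heavily skewed and contaminated by occasional aberrant
wells, so dose response is modelled on the conditional **median**:

    Median(y | D) = c + alpha*D + beta*D^2     (linear-quadratic, LQ)

fitted by quantile regression at tau = 0.5, i.e. by minimising the
pinball loss `sum_i r_i (tau - 1[r_i < 0])`.  The point fit is solved
**exactly** as a linear program (HiGHS via `scipy.optimize.linprog`):
minimise `tau*1'u+ + (1-tau)*1'u-` subject to `Xb + u+ - u- = y`.  The LP
returns a vertex solution; when the median is non-unique (more zero
residuals than coefficients) the fit carries a `degenerate` flag rather
than a second-stage norm-minimising solve — on the dose designs used
here (four distinct dose levels, n ≈ 1000) the optimum is unique in
practice.

Inference is a case-resampling bootstrap (default 1000 resamples, seeded).
Refitting thousands of resamples by LP is wasteful, so bootstrap refits
use a smoothed iteratively-reweighted least-squares (IRLS) path with
weights `|tau - 1[r<0]| / max(|r|, 1e-8)`, warm-started at the full-data
LP solution and run as one batched computation over all resamples
(batched 3×3 solves).  On bootstrap resamples of default cohorts the IRLS
and LP coefficient estimates agree to ~1e-4 in the worst replicate and
the resulting SEs agree to better than 2%; the tests additionally verify
LP-vs-IRLS agreement to 1e-6 on clean fixtures, and check the LP against
both a brute-force interpolation oracle (the median fit must pass through
p data points) and an independent quantile-regression implementation
(statsmodels `QuantReg`).

Standard errors are bootstrap SDs; the p-value for `beta = 0` is a
two-sided normal approximation `2*Phi(-|beta|/SE)`.  Because several
aliquots share a donor and are therefore correlated, the bootstrap
resamples **donors** (clusters) whenever donor identifiers are available,
implemented as multiplicity weights on rows so the whole batch stays
vectorised; without cluster labels it falls back to i.i.d. row
resampling.  Cluster resampling is what makes the k-calibration test
honest: an aliquot-level bootstrap understates the SE of the quadratic
term and rejects `beta = 0` too often at the true k.

## 3. k-calibration of the linearized index

`calibrate_k` scans k over an ascending grid (default 10, 20, …, 200 —
steps of 10), computes `Mi_BN_c(k)`, fits the LQ median model, and
selects the **first** k whose quadratic term is statistically consistent
with zero (two-sided bootstrap p > 0.05).  This operationalises an
incremental search a practitioner would run by hand.  If no grid value
qualifies, the k with the smallest |beta/SE| is returned and flagged
`converged=False`.

Under the generator's closure identity (section 4), the fitted quadratic
term as a function of k is

    beta(k) = beta_MiBN + (k_true / k) * (-beta_MiBN)

with `beta_MiBN = -0.0105 Gy^-2`: strongly **positive** at small k (the
MN/BN compensation term over-corrects), monotonically decreasing,
crossing zero exactly at `k_true`, and approaching `beta_MiBN < 0` as
k → ∞.  The sign change of the fitted beta therefore brackets the
selected k, which the property tests assert.

## 4. Synthetic cohort generator

The generator produces cohorts with the same *statistical skeleton* as
the 1122-aliquot study data set the package is designed around:

* ~155 donors × 9 aliquots (≈1395 scored rows, ≈1160 after filtering);
* doses {0, 3, 4, 8} Gy with weights (145, 541, 6, 430)/1122 — the
  post-filter composition, used for the pre-filter draw because the
  pre-filter composition is not published;
* ages 3–69 as a 50/50 mixture of uniform[3, 20] and uniform[21, 69]
  (young-skewed, median ≈ 21, matching a cohort with a pediatric arm);
  49.1% male; race probabilities (0.14, 0.066, 0.16, 0.634) for levels
  {0, 1, 2, 3} and ethnicity (0.38, 0.24, 0.38);
* median dose responses: yield `0.0163 + 0.00322 D + 0.00056 D²`;
  Mi_BN `0.0319 + 0.0960 D − 0.0105 D²`; Mi_BN_c target `0.200 + 0.0945 D`
  at `k_true = 70`.

**Closure identity.**  The MN/BN median is *derived* as
`k_true × (Mi_BN_c target − Mi_BN median)`, which makes the generator
self-consistent: computing `Mi/BN + (1/k_true)(MN/BN)` on noise-free
rates returns exactly the linear target, so the calibration of section 3
recovers `k_true` by construction, not by luck.  Within an aliquot the
micronucleus and mononucleated rates share one CBMN noise draw so the
identity holds per aliquot, not just in median.

**Counts.**  Scored-cell totals are negative binomial with dose-declining
means `MC ~ NB(800·e^(−0.15D))`, `BN ~ NB(500·e^(−0.20D))` and size
(dispersion) 0.95.  The size was tuned once so that the ≥20-cell filters
remove ≈17% of rows, reproducing the published 1349 → 1122 attrition;
with a less dispersed count model the sub-20 tail would be far too thin
to generate that exclusion rate.  Event counts are Poisson:
`dic ~ Pois(MC × yield rate)` (capped at MC), `mi ~ Pois(BN × Mi_BN rate)`,
`mono ~ Pois(BN × MN/BN rate)`.

**Heterogeneity and noise.**  Rates are the median curves times:

* a lognormal donor effect (log-SD 0.10, median 1, correlation 0.5
  between the DCA and CBMN effects — a shared radiosensitivity component
  plus assay-specific biology);
* an age multiplier `max(0.5, 1 + 0.004·(age − 25))` on both assays —
  yields tend to rise with age; the coefficient keeps the effect visible
  but secondary;
* a per-aliquot lognormal technical noise (log-SD 0.06, one draw per
  assay, shared by the two CBMN counts);
* **aberrant wells**: with probability 0.10 per assay per aliquot,
  independently, an extra lognormal factor of log-SD 0.8.  This emulates
  the occasional bad well of automated high-throughput scoring.  Because
  the factor is symmetric in log it leaves all medians unchanged (the
  calibration stages are unaffected), but it is what makes *neither assay
  sufficient alone*: a contaminated CBMN well can be rescued by its clean
  DCA measurement and vice versa, so the combined model beats either
  single-assay model — the central hypothesis the package exists to test.
  Without contamination the linearized CBMN index separates the discrete
  dose groups almost perfectly and adding DCA cannot help.

All lognormal terms have log-mean 0, so population medians equal the
configured curves (medians, unlike means, are preserved by symmetric
log-scale noise).  The per-dose sample medians sit ~2% above the nominal
curves — the net of Poisson count discreteness and the skewed age
multiplier convolved with symmetric noise — well inside one bootstrap SE
of the fits.

**What the generator does not emulate**: imaging artifacts and scorer
error structure, inter-laboratory variation, radiation-quality
differences (photons and electrons are treated as equivalent low-LET),
dose-rate effects on yields (dose-rate category is assigned uniformly at
random, including for 0 Gy rows, and has no effect on generated
responses), and real-data feature correlations beyond the shared donor
effect.  Passing tests on synthetic cohorts therefore demonstrate that
the *pipeline machinery* recovers known structure under realistic noise;
they do not certify real-data performance numbers.

## 5. Dose regression

The principal model is a **quantile regression forest**: bagged
scikit-learn trees whose leaves keep their bootstrap training targets.
Mean prediction is the average over trees of leaf means; conditional
quantiles are type-1 weighted empirical quantiles of the training
targets under Meinshausen weights (bag multiplicity in the query's leaf,
normalised by leaf size, averaged over trees).  Consequences asserted as
invariants: quantiles are non-decreasing in tau, and no prediction (mean
or quantile) can leave the training dose range — the forest cannot
extrapolate.

The default configuration mirrors the best-performing published setup:
500 trees, `mtry = 6`, `min_node_size = 1`, and the extremely-randomized
("extratrees") split rule, implemented as uniformly random thresholds
with best-of-mtry selection by variance reduction.  `mtry` larger than
the feature count is clamped with a warning.

Baselines (linear regression, elastic net, SVR, LightGBM boosted trees,
and a small model tree with ridge leaves) sit behind one adapter
interface and are compared under repeated k-fold cross-validation
(fivefold; 30 repeats in the full protocol, 5 in the reduced default) on
the training quarter, with grid search on the evaluation quarter and
final metrics on the withheld half.  R² is reported as the **squared
Pearson correlation** between actual and reconstructed dose (the study's
definition; scale/shift invariant), alongside the conventional
1 − SSres/SStot.

## 6. Feature selection (shadow features)

`run_boruta` appends a freshly shuffled shadow copy of every feature each
iteration, fits a variance-split forest, and computes out-of-bag
permutation importances.  A feature scores a hit when it beats the *best*
shadow.  Decisions use two-sided binomial tests against p = 0.5 with
Bonferroni correction across features: significantly more hits than
chance → confirmed, significantly fewer → rejected, otherwise tentative.
Only rejected features are dropped downstream (tentative features are
retained).  On default synthetic cohorts the assay indices are confirmed
and sex — generated with no effect — is rejected or tentative; weak real
effects (age, demographics) often land rejected/tentative against the
max-shadow hurdle at these cohort sizes, which is the expected behaviour
of the algorithm for borderline predictors.

## 7. Interpretation

`exact_shap` computes Shapley values by full coalition enumeration with
an interventional value function: v(S) is the prediction averaged over a
seeded background sample with features in S taken from the explained row.
This is exact for the ≤10-feature models used here, and one-hot blocks
can be declared as coalition *groups* (race, ethnicity) so a categorical
enters as a unit — the pipeline explains 6 groups, 64 coalitions.  Local
accuracy (base value + SHAP sums = prediction) holds to 1e-9 and the
implementation is tested for exact equality (1e-12) against an
independent all-orderings permutation oracle.  ICE curves sweep one
feature over a grid per sample; partial dependence is their pointwise
mean; 2-D PD surfaces average over rows on a grid pair.

## 8. Evaluation and ablation

`regression_metrics` reports MAE, RMSE (RMSE ≥ MAE always), both R²
variants, per-dose error breakdowns, and absolute-error percentiles
(50/75/80).  `quantile_coverage` counts actual doses inside predicted
quantile intervals (inclusive); with near-discrete dose targets the
pooled leaf quantiles usually contain the exact dose, so [q25, q75]
coverage runs far above its nominal 50% — the same behaviour the study
reports on real data — and the tests assert coverage ≥ nominal mass and
monotone widening rather than exact calibration.

Ablations retrain the model without the removed features on identical
training rows (permutation mode is also available) and compare paired
squared errors on identical test rows with a two-sided Wilcoxon
signed-rank test (`scipy.stats.wilcoxon`; zero differences dropped,
exact null for ≤25 tie-free pairs, tie/continuity-corrected normal
approximation otherwise; an all-zero difference vector is degenerate with
p = 1).  Default removal sets: {Mi_BN}, {Mi_BN, Mi_BN_c}, {yield}.

## 9. Pipeline and problem sizes

`run_pipeline` chains simulate → filter → calibrate → select → compare →
train → evaluate → explain under a single seed and writes JSON/CSV
reports plus a plain-text summary; identical configurations produce
byte-identical reports (no timestamps, sorted keys, seeded randomness
everywhere).  The reduced default configuration — 5×5 CV, 200 trees,
300 bootstrap resamples, 30 Boruta iterations — was chosen so a full run
takes on the order of a minute on one CPU while leaving every
statistical conclusion unchanged relative to the full protocol (5×30 CV,
500 trees, 1000 resamples); the full protocol is one config object away.

## 10. Known limitations

* The LP fit reports a vertex solution without a minimum-norm refinement
  for degenerate medians (flagged instead).
* Exact SHAP is limited to 10 features/groups by design; no sampling
  fallback is provided.
* The boosted-trees baseline is LightGBM only; other boosting libraries
  are easy adapters but out of scope.
* Synthetic cohorts make no claim about absolute real-data performance
  metrics (R², RMSE on the deposited data set); they validate recovery
  of the configured structure.
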