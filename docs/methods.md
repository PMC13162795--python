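# Methods note

This note records the mathematical definitions, modelling assumptions,
parameter choices and known limitations of the `mmfde` package. Symbols:
`M` is the number of base classifiers (4), `S ∈ [0,1]^M` a sample's
vector of positive-class confidences, `w` the metric weight vector, `β`
the membership decay constant.

## 1. Base ensemble

Four gradient-boosted classifiers are trained on identical preprocessed
features:

| model | library | key settings |
| --- | --- | --- |
| `lightgbm` | LightGBM | 200 trees, learning rate 0.05, max depth 6, L1 = L2 = 0.1, subsample 0.8, seed 42 |
| `xgboost` | XGBoost | 200 trees, learning rate 0.05, max depth 6, L1 = L2 = 0.1, subsample 0.8, seed 42 |
| `gbm` | scikit-learn `GradientBoostingClassifier` | 200 trees, learning rate 0.05, max depth 5, subsample 0.8, seed 42 |
| `adaboost` | scikit-learn `AdaBoostClassifier` | 200 stumps, learning rate 0.05, seed 42 |

Preprocessing (`ClinicalPreprocessor`) is fitted on training rows only:

- **Zero-as-missing imputation.** In Glucose, BloodPressure,
  SkinThickness, Insulin and BMI a recorded 0 is treated as missing and
  replaced by the median of the *non-zero training* values of that
  column. Zero is physiologically impossible for these measurements, so
  this is an encoding convention, not a value.
- **Min–max scaling** to the training range. Held-out values outside the
  training range are *not* clipped; they map outside `[0, 1]`, which the
  tree models tolerate and which avoids silently hiding covariate shift.

Both steps use training statistics exclusively, so no information leaks
from evaluation rows into the fitted transform.

## 2. Fusion

### 2.1 Deviation vectors and ideal references

The positive ideal is the all-ones confidence vector, the negative ideal
all-zeros. Deviations are `P_pos = 1 − S` and `P_neg = S − 0 = S`.

### 2.2 Distance metrics (normalized convention)

The package's primary convention normalizes each metric to `[0, 1]` so
that the convex combination is a like-for-like blend:

- Euclidean: `‖P‖₂ / √M`
- Manhattan: `‖P‖₁ / M`
- Cosine: `1 − cos(P, 1)` where `1` is the uniform direction. When
  `P = 0` (the sample *is* the ideal) the angle is undefined and the
  distance is set to 1: direction information is absent, which the
  convention treats as maximal directional dissimilarity. Because the
  magnitude metrics dominate the weights, this boundary choice has no
  practical effect on decisions near the ideals.
- Chebyshev: `max_i |P_i|` (already bounded).

Raw, unnormalized metrics (plain `‖·‖₂`, `‖·‖₁`) are available via
`normalize=False` on the fusion functions, the `FuzzyDistanceFusion`
estimator and the CLI flag `--raw-distances`. Raw and normalized hybrids
generally produce different decisions; the normalized form is the default
and the only one the worked example and tests pin numerically.

### 2.3 Hybrid distance, membership, score

```
Λ_j  = w_E d_E(j) + w_M d_M(j) + w_C d_C(j) + w_Ch d_Ch(j),  j ∈ {pos, neg}
μ_j  = exp(−β Λ_j)
score = exp(μ_pos) / (exp(μ_pos) + exp(μ_neg)) = 1 / (1 + exp(μ_neg − μ_pos))
```

Defaults: `w = (0.30, 0.30, 0.20, 0.20)`, `β = 2.0`. The score is a
two-way softmax over memberships; since `μ ∈ (0, 1]`, the score is
confined to roughly `(0.27, 0.73)` — it is an *ordering* and *margin*
device, not a probability. `score ≥ 0.5 ⇔ μ_pos ≥ μ_neg ⇔ Λ_pos ≤ Λ_neg`,
so the decision equivalently picks the nearer ideal. Exact ties resolve
to the positive (diabetic) class, the conservative triage direction.

Confidence bands act on `μ_max = max(μ_pos, μ_neg)`:
VeryHigh for `μ_max > 0.9`, High for `0.7 < μ_max ≤ 0.9`, Moderate for
`μ_max ≤ 0.7`.

### 2.4 Cosine non-monotonicity (caveat)

The three magnitude metrics are monotone: increasing any single model's
positive confidence never increases the corresponding deviation norm.
The cosine metric is **direction-only** and is *not* monotone in this
sense. Counterexample: with `S = (0.125, 0.125, 0.0625, 0.0625)`,
raising model 1's confidence to `0.375` rotates the deviation vector
*away* from the uniform direction and increases `d_C(pos)` from ≈0.051
to ≈0.228. Consequently the hybrid `Λ_pos` is only guaranteed monotone
when `w_C = 0`; with the default `w_C = 0.2`, non-monotone behavior is
possible though rare in practice (it needs a strongly unbalanced
confidence pattern). The test suite pins both facts: monotonicity of the
hybrid at `w_C = 0`, and the counterexample above.

### 2.5 Numerical choices

All fusion arithmetic is vectorized float64. `exp(−βΛ)` cannot overflow
for the supported `β ∈ [0.5, 5]` and bounded `Λ`; the score's logistic
form `1/(1+exp(μ_neg − μ_pos))` is used rather than the two-exponential
ratio for stability, and non-finite intermediates raise with the sample
index named.

## 3. Tuning

- **Weight search.** Exhaustive enumeration of the four-part simplex
  grid at step 0.05 (1771 candidates; 10 at step 0.5, 4 at step 1.0),
  scored by mean stratified k-fold accuracy of the fused decision. Per
  fold, the four distance components are computed once and each
  candidate is a dot product, so the full sweep is cheap. Ties break
  toward the maximum-entropy (most balanced) candidate, then
  lexicographically — the search is deterministic.
- **β search.** Grid `{0.5, 1.0, …, 5.0}`, scored by binary
  cross-entropy of the fuzzy score on a stratified 20% validation slice
  of the training partition; ties go to the smaller β. Weights are tuned
  first at β = 2; this sequencing is benign because the hard decision is
  invariant to β (it only rescales both memberships' exponents).
- **Stability surface.** Accuracy over the `(w_E, w_M)` slice with the
  remaining mass split equally between cosine and Chebyshev; the
  infeasible region `w_E + w_M > 1` is reported as NaN.

## 4. Evaluation and statistics

- Accuracy, precision, recall, F1 from integer confusion counts;
  undefined ratios (empty denominators) return NaN with a logged
  warning rather than a silent 0.
- ROC AUC and average precision via scikit-learn; both require both
  classes present.
- **5×2cv paired t-test** (Dietterich): five replications of stratified
  2-fold CV; `t = d₁⁽¹⁾ / sqrt(mean per-replication variance)` with 5
  degrees of freedom; zero variance across all folds is flagged
  degenerate with p = 1.
- **McNemar.** The continuity-corrected statistic
  `(|b−c|−1)²/(b+c)` (floored at 0) is always reported. With fewer than
  25 discordant pairs the p-value comes from the exact binomial test;
  otherwise from the χ²(1) tail. No discordant pairs → p = 1, flagged.
- **Bonferroni**: adjusted threshold `α/k` (0.05/8 = 0.00625 for the
  package's eight-comparison layout).
- **Bootstrap**: seeded percentile bootstrap
  (`np.random.default_rng(seed)`, `rng.integers(0, n, n)` per
  iteration); resamples collapsing to one class are redrawn when the
  metric needs both.
- **Calibration**: expected calibration error over 10 equal-width bins
  on `μ_max` by default (the quantity the triage bands act on), with
  `axis="fuzzy_score"` as an alternative; reliability bins and the
  VeryHigh/High/Moderate distribution are reported alongside.
- **Ablation**: leave-one-metric-out with the removed weight
  redistributed proportionally over the remaining metrics; removing a
  metric that carries all the weight is an error.

## 5. Interpretability

Shapley attributions are computed **exactly** by enumerating all `2^m`
feature coalitions (`m = 8`), with absent features marginalized over a
background sample of at most 32 training rows (interventional
expectation). Exact enumeration was chosen over a sampling approximator
because at 8 features it is fast (256 coalition evaluations), makes
additivity exact (`base + Σφ = output`, asserted to 1e−4 in tests), and
removes a source of run-to-run noise. Two explanation targets:

- `per_model_mean`: the mean positive-class probability of the four base
  models — attributions of the ensemble's raw belief.
- `fused_model_agnostic`: the end-to-end fuzzy score — attributions of
  the full distance-fusion pipeline.

Global importance is the mean absolute attribution (ties alphabetical).
Rank stability across folds is the mean pairwise Kendall τ restricted to
the union of top-k features. Concordance compares the sign of each
sample's dominant attribution with the geometric call
(`Λ_pos < Λ_neg`); samples whose attributions are all exactly zero are
excluded, and misclassification rates are reported per stratum.

## 6. Synthetic cohort generator

The generator is a **study tool, not a population model**. Marginals are
independent truncated normals inside physiological ranges (glucose mean
120 sd 30 on [44, 199], age mean 38 sd 12 on [21, 81], etc.; pregnancies
and age rounded to integers). The outcome is Bernoulli with logit
`α + Σ βᵢ zᵢ + ε`, `z` standardized features,
effect hierarchy Glucose (2.0) > BMI (1.2) > DiabetesPedigreeFunction
(0.8) > the rest, `ε ~ N(0, noise_sd²)`. The intercept `α` is solved by
Brent's method so the expected prevalence matches the target (default
0.44); realized prevalence beyond three binomial standard deviations of
the target triggers a warning. Optional zero-inflation re-codes a random
fraction of the five zero-coded physiological columns to 0 *after* the
outcome is drawn, so missingness is non-informative by construction.
Feature correlations are not modelled; the generator supports method
verification and scaling studies (default n = 2000), not epidemiological
inference.

## 7. Known limitations

- The fuzzy score is bounded away from 0 and 1 and is not a calibrated
  probability; calibration is therefore assessed on `μ_max`.
- The cosine term breaks single-coordinate monotonicity of the hybrid
  distance (§2.4).
- Weight tuning optimizes fold accuracy, a step function; large plateaus
  of equally scoring candidates are common on small cohorts, which is
  why the entropy tie-break matters for determinism.
- Exact Shapley enumeration is capped at 16 features; beyond that a
  sampling approximator would be required.
- All empirical figures quoted in this repository (held-out accuracy and
  AUC in the README example) are computed from the package's own
  synthetic cohorts with the seeds shown; no claims are made about
  performance on external clinical datasets.
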