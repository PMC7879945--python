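# Methods

This note documents the statistical procedures, the simulation design, the
numerical conventions and the open design choices of `invsel`.

## The selection problem

Given a numeric feature matrix **X** (n samples × p features, p ≫ n possible)
and a per-sample classification *c* that may contain rater errors, the goal
is to select features associated with the *true* underlying grouping — which
the analyst never observes — and to train an interpretable (generalised)
linear model on them. The package implements two pre-selection strategies and
a benchmark that compares them on simulated data where the truth is known.

### V1: inverted-role screening

Each feature is treated as the dependent variable:

* **Univariate LRT.** For feature *x* the Gaussian linear model
  *x ~ 1 + c* is tested against *x ~ 1* with the likelihood-ratio statistic
  2(ℓ₁ − ℓ₀) = n · log(RSS₀ / RSS₁), referred to χ²₁. The classification
  enters as a single numeric regressor (1 df) for binary *and*
  semi-quantitative labels; this encodes the assumption that rating
  categories are equidistant. Optional covariates enter *both* models so the
  test isolates the classification term. A factor-style encoding is not the
  default and not used by the benchmark.
* **Multiplicity.** P-values are adjusted (Benjamini–Hochberg by default;
  Bonferroni and Holm available) and cut at adjusted p < α = 0.05, strict
  inequality. An empty survivor set is a legitimate outcome and is treated
  downstream as "no model can be built from these labels".
* **Inverted-role CV.** Survivors are ranked by seeded k-fold (default k=3)
  cross-validation error of the same inverted model *x ~ c*; the best
  min(#survivors, n) features are retained, ties broken by original feature
  order so runs are reproducible.

The rationale: a model forced to predict noisy labels rewards features that
fit the errors; testing whether the labels explain each feature, under
family-wise or FDR control, admits only features with a reproducible
association and refuses to produce a model when the labels carry no signal.

### V2: standard CV ranking (baseline)

Each feature is scored by univariate prediction of the classification:
k-fold CV accuracy of the logistic model *c ~ x* for binary labels (held-out
probabilities thresholded at 0.5; default k=10 following the convention of
the classical binary-CV helper) or k-fold CV mean squared error of the
linear model (default k=3) for graded labels. The top n features are kept.
V2 always returns min(p, n) candidates — its inability to return "nothing"
is the behaviour the benchmark exposes.

### Model building

The retained features enter a logistic (binary) or Gaussian
(semi-quantitative) model reduced by backward stepwise search: every round
scores each single-term deletion by the criterion and accepts the best
deletion if it strictly improves on the current model; the intercept is
never removed. Criteria: AIC = −2ℓ + 2k (default), BIC = −2ℓ + log(n)·k, or
k-fold CV error (misclassification rate / MSE) with the folds drawn once per
round so candidate comparisons are paired. The Gaussian log-likelihood is
the profile form −n/2·(log 2πRSS/n + 1) and k counts mean parameters
(intercept included, variance not), matching the standard stepwise
convention; the reported criterion values agree with statsmodels' AIC/BIC
conventions, which the tests assert.

Numerical conventions that matter in the p ≈ n regime:

* The effective parameter count is capped at n (the attainable design rank
  for generic continuous features); exactly aliased columns are detected by
  pivoted QR and dropped with a warning before fitting.
* A Gaussian fit with numerically zero residual (RSS below 10⁻¹² of the
  outcome's scale) is *saturated*: its criterion is −∞ and the search stops
  there, mirroring how stepwise selection behaves on an interpolating linear
  model. Its predictions are the observed labels.
* Logistic fits use Newton/IRLS with step-halving and linear predictors
  clamped to ±30, so complete separation converges to a bounded fit instead
  of diverging — separated fits are accepted, as they are by the reference
  GLM machinery this mirrors, and the convergence flag feeds the benchmark's
  definition of a *successful fit*: at least one feature selected and a
  converged final model.

### Evaluation

Model scores (in-sample fitted probabilities or linear predictions) are
compared against the **true** labels with the Mann–Whitney AUC (ties count
1/2). Two orientations are provided:

* `direction="fixed"` — higher score ⇒ class 1, never flipped;
* `direction="auto"` — the orientation is chosen by comparing class medians
  first (flip when the negative class has the higher median), the default
  convention of the standard ROC tooling. This is a heuristic, not a
  maximisation: AUCs at and below 0.5 still occur, and the benchmark indeed
  records them for V2.

The benchmark uses `auto`: with inverted label conventions (e.g. error
probabilities 0.9/0.1 the observed labels are mostly the complement of the
truth) a trained model is anti-oriented by construction, and the auto rule
scores its discrimination rather than its sign. For more than two classes
the Hand–Till-style multiclass AUC averages the pairwise binary AUC of the
single score vector over all unordered class pairs; it reduces exactly to
the binary AUC for two classes. AUC ranks across pipeline variants use
average or seeded-random tie resolution.

## Simulation design

One condition draws n samples in g balanced groups (an uneven remainder goes
entirely to the highest group), p features of which each is independently
informative with probability 0.10. Informative feature j in group k is
N(base + k·Δ, σ) — adjacent group means differ by the constant Δ — and
non-informative features are N(base, σ) for all samples, so selection
difficulty is governed solely by Δ/σ; `base` defaults to 0 (only differences
matter to every procedure in the package). Observed classifications:

* **binary** (g = 2): observed label ~ Bernoulli(prob1) for true group 0,
  Bernoulli(prob2) for true group 1. (0, 1) is the error-free corner;
  prob1 = prob2 destroys all label information; (0.9, 0.1) inverts the
  convention.
* **semi-quantitative, graduated truth** (g = c categories): the true rating
  is the group index; the observed rating is |true − e| with
  e ~ Bernoulli(prob1), so category 0 flips up to 1 and any c ≥ 1 drops one
  step.
* **semi-quantitative rating of a two-group truth** (g = 2, c > 2): the
  observed rating is Binomial(c − 1, p) with p = prob1 / prob2 per true
  group — the direct c-category generalisation of the binary per-group
  scheme (its c = 2 special case). A larger scale concentrates the rating
  around (c−1)p, so unequal probabilities become *more* informative with
  more categories, while prob1 = prob2 again destroys all information.

A master seed drives independent sub-streams for the informative mask, the
feature matrix and the label errors, so each stage is reproducible on its
own and a fixed seed reproduces a dataset bit-for-bit. A condition whose
observed labels collapse to a single value (possible at extreme
probabilities) is counted as a failed fit for both pipelines.

What the generator deliberately does not emulate: unbalanced groups,
correlated features, non-normal feature distributions, and feature effects
of heterogeneous sign or size. Passing benchmarks therefore demonstrate
behaviour under independent, homoscedastic, equidistant-mean signal — not
robustness to real-data structure.

## Benchmark grids

* **Binary two-group**: 25 samples/group, 100 features, all 16 ordered
  (prob1, prob2) pairs from {0.1, 0.3, 0.6, 0.9}, effect grid
  Δ ∈ {1, 2, 3} × σ ∈ {1, 2, 3} — 144 conditions. The probability levels
  are the documented ones; the 3×3 effect grid is a reconstruction chosen to
  span weak (Δ/σ = 1/3) to strong (Δ/σ = 3) effects and to keep the 144
  condition count; it is fully overridable via `GridConfig`.
* **Semi-quantitative two-group**: 50 samples, 100 features, rating scales
  c ∈ {3, 4, 5}, same probability and effect grids.
* **Graduated**: 50 samples, 100 features, k = c ∈ {3, ..., 10} groups,
  graded errors with prob1 ∈ {0.1, 0.3, 0.6, 0.9}.
* **Large-scale (scaled down)**: 2,000 features, 50 samples/group, the
  weakly informative probability pairs (0.1, 0.3)/(0.3, 0.1), Bonferroni
  adjustment. This is a deliberate reduction of the original up-to-10,000
  features / 100 samples-per-group setting so the whole benchmark runs in
  minutes on one CPU; medians under this scaling are reproduced with a
  wider tolerance.

`scripts/acceptance.py` runs all four grids with three seeded replicates per
condition and reports medians, minima, the fraction of V2 models with
AUC ≤ 0.5 (inclusive), and V1's successful-fit fraction relative to V2
(median over category strata).

## Interpretation notes and known limitations

* **Minima are extreme order statistics.** The minimum AUC over successful
  V1 fits is dominated by rare single-feature models built from multiplicity
  false positives at uninformative probability pairs (family-wise error
  ≈ α per condition guarantees a few across hundreds of null conditions).
  Their AUC against the truth is ≈ 0.5. Any run with several replicates
  will therefore report V1 minima near 0.5 in grids that contain
  uninformative label conditions; single fixed-seed runs can easily miss
  all of them. Medians and fractions are the stable summaries.
* **V2's low-AUC share.** V2 models at or below AUC 0.5 arise mostly from
  the pure-noise diagonal probability pairs, where the fitted scores track
  the observed labels and their AUC against the truth fluctuates around
  0.5; roughly half of those conditions fall at or below it. Weakly
  informative pairs contribute additional cases through overfitting noise,
  so the measured share is sensitive to the weak-effect cells of the
  reconstructed grid.
* The χ²₁ reference for the screening LRT is mildly anti-conservative at
  n = 50 (the exact finite-sample reference would be an F tail); the
  family-wise error of the Bonferroni screen measures ≈ 0.05–0.08 rather
  than exactly α, which the calibration test allows for.
* Timing per condition is recorded in the benchmark tables but is
  hardware-dependent and never asserted.
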