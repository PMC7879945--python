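# invsel

Feature selection and model building for samples whose classification may be
wrong.

## The problem

In translational omics studies a high-dimensional feature matrix (expression,
methylation, ...) is routinely modelled against a classification produced by
a human rater — a binary call (tumour subtype A/B) or a semi-quantitative
staining score (0–5). Rater classifications are noisy: inter-expert
discordance of 5–15% is commonly reported. Standard feature selection
optimises prediction of the *given* labels, so with noisy labels it rewards
features that track the errors rather than the true underlying groups.

`invsel` implements a pre-filtering heuristic (**V1**) that inverts the roles
of the variables before model building. For each feature *x<sub>j</sub>* and
observed classification *c*:

1. fit the linear models *x<sub>j</sub> = β₀ + β₁ c + ε* and
   *x<sub>j</sub> = β₀ + ε* and compute the likelihood-ratio test p-value
   *p<sub>j</sub>* = P(χ²₁ ≥ 2(ℓ₁ − ℓ₀));
2. adjust the *p<sub>j</sub>* for multiplicity (Benjamini–Hochberg or
   Bonferroni) and keep features with adjusted p < α = 0.05 — possibly
   *none*, which is itself an informative outcome;
3. rank the survivors by k-fold cross-validation error of the same
   inverted-role model and keep at most *n* (the sample count) of them;
4. hand the retained features to a standard model — logistic regression for
   binary *c*, a linear model for semi-quantitative *c* — reduced by backward
   stepwise selection under AIC (BIC and CV-error criteria are available).

The baseline (**V2**) is the conventional direction: rank every feature by
cross-validated univariate prediction of *c* (CV accuracy of
*c ~ x<sub>j</sub>* for binary labels, CV mean squared error for graded
labels), keep the top *n*, and build the same stepwise model. V2 always
returns a candidate set; it has no concept of "the labels carry no signal".

A simulation benchmark measures both pipelines by the AUC of their model
scores against the *true* grouping (Mann–Whitney AUC; Hand–Till pairwise
average for more than two classes), which only a simulation can know.

## Worked example

```python
import numpy as np
from invsel import (SimulationConfig, simulate_dataset,
                    InvertedRoleSelector, CVRankSelector, StepwiseGLM, auc_binary)

cfg = SimulationConfig(n_samples=50, n_features=100, mean_diff=3.0, sd=1.0,
                       prob1=0.1, prob2=0.9, seed=7)   # ~18% wrong labels
ds = simulate_dataset(cfg)
y = ds.observed_labels.astype(float)

v1 = InvertedRoleSelector(adjust="BH", random_state=1).fit(ds.features, y)
m1 = StepwiseGLM(random_state=1).fit(ds.features[:, v1.selected_idx_], y)
auc1 = auc_binary(m1.predict_scores(ds.features[:, v1.selected_idx_]),
                  ds.true_labels, direction="auto")

v2 = CVRankSelector(random_state=1).fit(ds.features, y)
m2 = StepwiseGLM(random_state=1).fit(ds.features[:, v2.selected_idx_], y)
auc2 = auc_binary(m2.predict_scores(ds.features[:, v2.selected_idx_]),
                  ds.true_labels, direction="auto")

print(f"informative features: {ds.informative_idx.size}, "
      f"V1 selected: {v1.n_selected_}, V2 selected: {v2.n_selected_}")
print(f"AUC vs ground truth  V1: {auc1:.3f}   V2: {auc2:.3f}")
```

Output:

```
informative features: 13, V1 selected: 13, V2 selected: 50
AUC vs ground truth  V1: 0.978   V2: 0.820
```

With 18% of labels wrong, the inverted-role screen retains exactly the 13
truly informative features and its model ranks samples by their true group
almost perfectly (AUC 0.98), while the standard CV ranking keeps 50
candidates, overfits the noisy labels, and recovers the truth less well
(AUC 0.82). Both selectors are scikit-learn transformers, so
`Pipeline([("select", InvertedRoleSelector()), ("model", StepwiseGLM())])`
works as usual.

The same workflow is available from the shell:

```bash
invsel simulate --n-samples 50 --n-features 100 --mean-diff 3 --sd 1 \
       --prob1 0.1 --prob2 0.9 --seed 7 --out data/
invsel prefilter --features data/features.tsv --meta data/meta.tsv \
       --adjust BH --seed 1 --out prefilter.tsv
invsel fit --features data/features.tsv --meta data/meta.tsv \
       --selected prefilter.tsv --type lr --seed 1 --out model.json
invsel predict --model model.json --features data/features.tsv --out scores.tsv
invsel evaluate --scores scores.tsv --meta data/meta.tsv --direction auto \
       --truth-col true_label --out eval.json
invsel benchmark --preset binary_2group --seed 1 --out results/
```

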