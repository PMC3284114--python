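# cbal — class-balanced active learning for binary classifiers

Supervised classifiers in biomedical image analysis are often trained on
pools where the target class is rare: in digitized histopathology,
cancerous image regions may make up only ~4% of the annotated patches
(a ~25:1 class ratio). Building a training set by random annotation then
wastes expert effort on uninformative majority-class samples and yields a
biased classifier — the *minority class problem*.

`cbal` implements a training strategy that attacks both issues at once:

* **Query-by-committee active learning.** A committee of *M* bagged
  decision trees assigns each unlabeled sample a confidence
  *T(r) ∈ [0, 1]* (the fraction of members voting for the minority class
  ω₁). Samples with *|T(r) − 0.5| ≤ τ* — those the committee disagrees
  about — form the *eligible set* S^E and are the only annotation
  candidates. τ = 0.5 makes every sample eligible, recovering random
  learning.
* **Class-balanced annotation.** Eligible samples are annotated uniformly
  at random until per-class quotas (k̂₁ minority, k̂₂ majority) are met.
  Surplus annotations are cached and reused free at later iterations, so
  no expert call is ever wasted or double-counted.
* **A negative-binomial cost model.** If a fraction *p* of the candidates
  is minority-class, the number of annotations *N* needed to observe k̂₁
  minority samples follows
  *P(N = n) = C(n−1, k̂₁−1) p^{k̂₁} (1−p)^{n−k̂₁}*.
  The model predicts per-iteration cost (mean k̂₁/p, or the P_Δ-quantile
  for a confidence-level budget), updates *p* as the pool is depleted via
  *p′ = (k₁ − k̂₁)/(k₁ + k₂ − N)*, and sums the per-iteration costs into
  the total training cost *L = Σₜ Nₜ*.

The package also ships the comparison baselines (unbalanced active
learning, class-balanced and unbalanced random learning, full training),
a pluggable boosted-tree evaluation classifier with ROC/AUC and
Youden-operating-point accuracy, patch texture features (first-order
statistics, 13 Haralick co-occurrence statistics, a 40-filter Gabor
bank), and synthetic data generators — both feature-space pools and
textured image patches — so every component runs with known ground truth
and no external dataset.

## Worked example

```python
import numpy as np
from cbal import (PoolSpec, RunConfig, make_feature_pool, split_pool,
                  run_strategy, predict_cost_curve)

# a pool like the study setting: 12,588 samples, 4% minority
dataset = make_feature_pool(PoolSpec(n_total=12588, minority_fraction=0.04,
                                     class_separation=2.0, dim=14, seed=1))
train, test = split_pool(dataset, 1346 / 12588, seed=2)

cbal_trace = run_strategy(train, RunConfig(strategy="cbal", T=40, tau=0.25,
                                           k1_hat=1, k2_hat=1, seed=3,
                                           eval_every=0), test_pool=test)
ubrl_trace = run_strategy(train, RunConfig(strategy="ubrl", T=40, K=2, seed=3,
                                           eval_every=0), test_pool=test)
for name, tr in [("CBAL", cbal_trace), ("UBRL", ubrl_trace)]:
    last = tr.to_frame().iloc[-1]
    print(f"{name}: 80 added samples, cost L={last.L:.0f}, "
          f"test AUC={last.auc:.3f}")
```

prints

```
CBAL: 80 added samples, cost L=614, test AUC=0.848
UBRL: 80 added samples, cost L=80, test AUC=0.507
```

Both strategies add 80 samples over 40 iterations, but CBAL's training
set holds 40 minority exemplars (versus ~3 under random annotation), and
its test AUC is far closer to the full-training ceiling. The price is
annotation cost: maintaining a 1:1 ratio at 4% prevalence costs ~25
annotations per iteration, which is exactly what the cost model
predicts:

```python
curve = predict_cost_curve(p0=0.04, k1_hat=1, k2_hat=1, T=40,
                           pool_size=11242, statistic="mean")
print(curve.head(3).to_string(index=False))
#  t      p_t  predicted_N_t  cumulative_L
#  1 0.040000      25.000000     25.000000
#  2 0.040029      24.982183     49.982183
#  3 0.040029      24.982183     74.964365
```

A command-line surface wraps the same functionality:
`cbal simulate-pool`, `cbal simulate-images`, `cbal featurize`,
`cbal train`, `cbal predict-cost`, `cbal evaluate`, `cbal compare` and
`cbal run --config <yaml>` (presets `experiment1/2/3` mirror the three
study harnesses). See `docs/methods.md` for the model details, defaults
and limitations.

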