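# Methods

## The training problem

A binary classifier must be trained from an unlabeled pool S^tr in which
the target (minority) class ω₁ is rare — the motivating setting is
cancer detection on digitized tissue, where ~4% of image regions are
cancerous. Annotation is expensive, so the package treats training-set
construction as a sequential decision problem: at each iteration *t* a
strategy chooses which samples an oracle should label, the labeled batch
moves from the pool into the training set, and the number of oracle
calls is metered as the cost N_t.

Five strategies are implemented. The headline strategy (class-balanced
active learning) combines two mechanisms; the other four ablate them.

### Query-by-committee eligibility

A committee of M decision trees is trained on the current labeled set,
each member on an independent bootstrap resample (bagging). The fuzzy
confidence T(r) is the fraction of members voting ω₁; the eligible set
at margin τ is {r : |T(r) − 0.5| ≤ τ}. The inequality is inclusive so
that τ = 0.5 makes the whole pool eligible — with everything eligible
and quotas enforced, the active strategy is *identical in law* (and, in
this implementation, identical draw-for-draw under shared seeds) to
class-balanced random learning. τ = 0 keeps only samples at exact vote
parity, attainable only for even M.

Choices where the design was open:

* **M = 10 by default.** The committee size is a free parameter; 10 is a
  standard query-by-committee ensemble size, and an even M makes exact
  0.5 disagreement attainable. Configurable via `RunConfig.m`.
* **Unpruned trees** (no depth cap by default): "weak" members are not
  quantified anywhere authoritative; bagging supplies the variance the
  disagreement signal needs. A `max_depth` cap is exposed.
* Member bootstrap resamples that miss a class entirely are redrawn, so
  every member is a genuine two-class voter.

### Balanced annotation (the minority-class query)

Eligible samples are drawn uniformly at random *without replacement* and
annotated until the batch holds exactly k̂₁ minority and k̂₂ majority
samples. A sample whose class quota is already full is *surplus*: the
annotation fee is already spent, so the sample is parked in a per-class
cache and consumed — free — before any new draw at later iterations.
This is the cost-minimizing reading of "surplus annotations can be kept
for later"; the audit log records each event's source
(`eligible`/`cache`/`fallback`) so cost traces remain interpretable.
Only genuine oracle calls count toward N_t; cache-satisfied quota slots
are zero-cost by construction, and the oracle raises on any attempt to
charge the same sample twice.

If the eligible set is exhausted before the quotas fill, drawing falls
back to the full unlabeled pool (enabled by default, logged) — the
graceful degradation of active learning to random sampling in the worst
case. With fallback disabled the query raises, carrying the partial
batch.

### The strategy grid

| strategy | eligibility | class quotas |
|----------|-------------|--------------|
| cbal     | committee, margin τ | enforced (k̂₁, k̂₂) |
| ubal     | committee, margin τ | none (first K random eligible) |
| cbrl     | whole pool  | enforced |
| ubrl     | whole pool  | none |
| full     | —           | entire pool labeled at once |

Every run starts from a bootstrap set of `bootstrap_size` random
annotations (default 10), extended one draw at a time until both classes
are present — the smallest set that lets bagging function while keeping
the early iterations meaningful. The bootstrap's minority fraction is
the natural empirical estimate of p₀.

## The annotation-cost model

Under uniform random annotation from a candidate set with minority
fraction p, the annotations N needed to observe k̂₁ minority samples are
negative-binomial:

    P(N = n) = C(n−1, k̂₁−1) p^{k̂₁} (1−p)^{n−k̂₁},  n ≥ k̂₁.

`scipy.stats.nbinom` is the numerical backend; an exhaustive
sequence-enumeration oracle pins the pmf exactly in the tests.

Three per-iteration predictors are exposed (`statistic=`):

* `"mean"` — k̂₁/p, the distribution's expectation; the right curve to
  compare against *trial-averaged* observed costs.
* `"quantile"` (default for budgeting) — the smallest N whose CDF
  reaches the model confidence P_Δ: the annotation budget that meets the
  minority quota with probability ≥ P_Δ. P_Δ defaults to 0.95 and is
  configurable; it is a user-chosen certainty level, not an estimated
  quantity.
* `"as_printed"` — the literal minimization form: the N in
  [k̂₁, |pool|] whose *pmf* is closest to P_Δ (smallest N on ties).
  Retained for completeness; the quantile form is the cumulative reading
  of "certainty that the quota is met within N annotations" and is the
  default.

Every curve prediction is floored at the batch size k̂₁ + k̂₂ (with no
cache, an iteration must annotate at least its quota — hence a pool of
pure minority samples still predicts N = 2 for quotas (1, 1)) and capped
at the remaining pool size. p = 0 predicts annotating the whole pool,
with a warning.

Across iterations the minority fraction drifts: each balanced iteration
removes k̂₁ minority samples among N_t annotations, so

    p_{t+1} = (k₁,t − k̂₁) / (k₁,t + k₂,t − N_t),

which is 0 once the minority class is exhausted and undefined (raised)
when the pool empties. In simulation the counts k₁,t, k₂,t are the known
pool composition (`update_source="oracle_counts"`); in deployment they
are unobservable and are estimated as p_t·|pool| and (1−p_t)·|pool|
before the update (`"running_estimate"`). The two coincide whenever
p₀·|pool| is an integer.

## Evaluation

Training sets are scored by an independent classifier — a gradient
boosted-tree ensemble (depth-2 stumps, 100 rounds), deliberately a
different learner from the bagged committee so selection and evaluation
do not share inductive biases. Any probabilistic scorer satisfying the
`fit_eval_classifier` contract (scores in [0, 1], deterministic under
seed) can be substituted.

The ROC curve sweeps the decision threshold θ over every distinct score
plus the endpoints {0, 1}, under the strict hard-label rule
ĝ(r) = 1 iff score > θ. AUC is the trapezoidal integral, which equals
the Mann–Whitney pairwise statistic with ties counted ½ (asserted
against a brute-force pair count in the tests). The operating point θ*
maximizes Youden's J = TPR − FPR, ties resolved toward the lower
threshold; reported accuracy applies the strict rule at θ*. The
closest-to-(0,1) convention was the plausible alternative; Youden was
chosen as the more common operating-point definition and the choice is
isolated in one place.

## Texture features

Regions (default 30×30 pixels) are summarized by the average of
pixel-wise feature responses:

* **First-order:** mean, median, population standard deviation, range,
  Sobel gradient-magnitude mean, directional gradient means. The
  pixel-wise window defaults to the region itself, so these reduce to
  one computation per region.
* **Haralick (13):** a symmetric gray-level co-occurrence matrix at
  distance 1, averaged over the four standard directions after
  quantization to 64 gray bins (the standard convention; both are
  configurable). The 13 classical statistics are computed on the
  normalized matrix with natural logarithms; sum variance is centered on
  the sum average. Degenerate point-mass matrices (constant patches)
  give energy 1, entropies 0, contrast 0 and correlation 1 by
  convention.
* **Gabor (40):** complex kernels at 5 frequencies × 8 orientations,
  each kernel's DC component removed so constant patches respond ~0.
  Responses are computed by FFT convolution over the full image with
  reflect padding (border responses come from mirrored content, not
  zeros) and the magnitude is averaged over each region.

A shipped 14-feature default selection — {std, range} first-order,
{information measure of correlation 1, correlation, energy, contrast,
entropy} Haralick, and the 7 orientations 0°–135° at frequency 0.2
cycles/pixel Gabor — stands in for a boosting-selected subset whose
exact member identities are not published; "contrast variance" in that
subset's description is ambiguous between one feature and two, and is
read here as "contrast". Any other subset of the 60-name registry can be
selected by name.

## Synthetic data

The generators define the study conditions for all tests and the
acceptance computation:

* **Feature pools:** two multivariate Gaussians with shared identity
  covariance, means separated by `class_separation` along a random unit
  vector — so separation is measured in noise units and directly sets
  the Bayes error. Defaults: 12,588 samples, 4% minority (the ~25:1
  ratio of the motivating dataset), separation 2.0 (Bayes AUC ≈ 0.92 —
  a difficult-but-learnable boundary, which active learning needs),
  dimension 14 (matching the feature selection). The minority count is
  deterministic (`round`), not binomial, so balance invariants are
  exactly testable. The train/test split defaults to 1,346 test /
  11,242 train.
* **Texture patches:** minority regions are an oriented sinusoidal
  grating (0.2 cycles/pixel, 45°, amplitude 40 gray levels) in Gaussian
  noise (σ = 20); majority regions are the noise alone. The classes
  therefore differ in second-order statistics by construction, and the
  Gabor filter matched to the grating separates them.

What the generators deliberately do not emulate: stained-tissue
appearance, spatial correlation between neighboring regions, H&E color
variation, heavy-tailed or multimodal class-conditional densities, and
label noise. Passing tests therefore demonstrate the correctness of the
algorithms and the cost model under their stated assumptions
(independent draws, fixed within-iteration prevalence), not classifier
performance on real histopathology.

## Numerical choices and degenerate inputs

* All randomness flows from one root seed through named, independent
  streams (query draws, committee bootstraps, bootstrap init,
  evaluation), so runs are bit-reproducible and strategies that should
  coincide (cbal at τ = 0.5 vs cbrl) consume the query stream
  identically.
* Eligibility uses |T − 0.5| ≤ τ + 1e-12 to keep exact boundary vote
  fractions inside the margin under floating-point representation.
* Co-occurrence matrices of single-level patches put all mass in one
  cell; every Haralick statistic remains defined (see above).
* `split_pool` always leaves at least one test sample; a pool-exhausting
  run truncates its trace (recorded, not fatal) and keeps the partial
  batch so that cost conservation — oracle calls = bootstrap charges +
  Σ N_t — holds in every run.

## Scale of the shipped computations

The test suite and the acceptance script run everything at the sizes
the package documents as defaults: the cost-model check uses the full
11,242-sample pool with 50 replicates of 40 iterations; the strategy
comparison uses 20 trials of the 12,588-sample pool at the
80-added-sample budget; Monte-Carlo checks of the negative-binomial
quantile use 10⁵ replicates. These sizes give Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

* The committee's confidence is a raw vote fraction, not a calibrated
  probability; τ is a rank-style margin, not a probability bound.
* The cost model assumes the within-iteration prevalence is fixed and
  draws are independent; with surplus caching the observed cost of the
  *majority* quota is largely hidden (cache-satisfied), so the model's
  minority-driven prediction slightly overstates cost at t = 1 and
  matches thereafter — visible, and small, in the acceptance output.
* Multi-class extension is out of scope; all machinery is binary.
* The evaluation classifier's absolute accuracy/AUC on synthetic pools
  says nothing quantitative about real histopathology data.
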