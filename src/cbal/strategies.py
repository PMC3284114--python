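"""Active / random training strategies and the comparison harness.

Five ways to build a training set from an unlabeled pool:

* **cbal** — class-balanced active learning: a bagged-tree committee
  flags informative samples (confidence within tau of 0.5) and the
  balanced query annotates them until each class quota is met;
* **ubal** — unbalanced active learning: the first K random eligible
  samples are annotated regardless of class;
* **cbrl** — class-balanced random learning: the whole unlabeled pool is
  eligible, quotas enforced;
* **ubrl** — unbalanced random learning: K random annotations per
  iteration, the classic baseline;
* **full** — every pool sample annotated at once (the ceiling).

Each run starts from a small bootstrap set (re-drawn until both classes
are present), loops for T iterations moving annotated batches from the
pool into the training set, and records a per-iteration trace:
training-set composition, annotations spent (N_t), cumulative cost L,
and — when a test pool is supplied — the evaluation accuracy and AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import STREAM_BOOTSTRAP, STREAM_COMMITTEE, STREAM_EVAL, STREAM_QUERY, child_rng, child_seed
from .balancer import AnnotationOracle, ExhaustionError, min_class_query, random_query
from .committee import find_eligible, train_committee
from .cost_model import total_cost
from .evaluation import evaluate_training_set
from .exceptions import SingleClassError, ValidationError
from .pool import MINORITY, LabeledSet, Pool
from .synthetic import PoolSpec, make_feature_pool, split_pool

logger = logging.getLogger(__name__)

STRATEGIES = ("cbal", "ubal", "cbrl", "ubrl", "full")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a single training run.

    For balanced strategies the per-iteration batch is k1_hat minority +
    k2_hat majority (K = k1_hat + k2_hat); unbalanced strategies annotate
    K samples regardless of class.  ``delta`` is the stopping-criterion
    threshold applied to recorded accuracy traces; ``eval_every`` = 0
    evaluates only the final iteration.
    """

    strategy: str = "cbal"
    T: int = 40
    tau: float = 0.25
    k1_hat: int = 1
    k2_hat: int = 1
    K: int | None = None
    m: int = 10
    delta: float = 0.01
    seed: int = 0
    bootstrap_size: int = 10
    max_depth: int | None = None
    eval_every: int = 1
    fallback: bool = True

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"strategy must be one of {STRATEGIES}")
        if self.T < 1:
            raise ValidationError("T must be >= 1")
        if not 0.0 <= self.tau <= 0.5:
            raise ValidationError("tau must be in [0, 0.5]")
        if self.balanced and self.K is not None and self.K != self.k1_hat + self.k2_hat:
            raise ValidationError("for balanced strategies K must equal k1_hat + k2_hat")

    @property
    def balanced(self) -> bool:
        return self.strategy in ("cbal", "cbrl")

    @property
    def batch_size(self) -> int:
        if self.balanced:
            return self.k1_hat + self.k2_hat
        return self.K if self.K is not None else self.k1_hat + self.k2_hat


@dataclass
class RunTrace:
    """Per-iteration records plus the final training set of one run."""

    records: list = field(default_factory=list)
    training_set: LabeledSet | None = None
    committee: object = None
    bootstrap_cost: int = 0
    config: RunConfig | None = None
    truncated: bool = False

    def to_frame(self) -> pd.DataFrame:
        cols = ["t", "n_minority", "n_majority", "added_minority", "added_majority", "N_t", "L", "accuracy", "auc"]
        return pd.DataFrame(self.records, columns=cols)

    @property
    def total_cost(self) -> int:
        return total_cost(r["N_t"] for r in self.records)


def bootstrap_init(pool: Pool, oracle: AnnotationOracle, size: int = 10, seed: int = 0) -> LabeledSet:
    """Random initial training set, re-drawn until both classes appear.

    Draws ``size`` samples uniformly without replacement and annotates
    them (cost charged); if a class is missing, keeps appending single
    random draws until both classes are present.
    """
    if len(np.unique(pool.y)) < 2:
        raise SingleClassError("pool contains a single class; cannot initialize")
    if size < 2:
        raise ValidationError("bootstrap size must be >= 2")
    rng = child_rng(seed, STREAM_BOOTSTRAP)
    order = rng.permutation(len(pool))
    labeled = LabeledSet()
    k = 0
    for k in range(size):
        i = order[k]
        lab = oracle.annotate(pool.ids[i], iteration=0, source="bootstrap")
        labeled.add(pool.ids[i], pool.X[i], lab)
    k = size
    while not labeled.has_both_classes() and k < len(pool):
        i = order[k]
        lab = oracle.annotate(pool.ids[i], iteration=0, source="bootstrap")
        labeled.add(pool.ids[i], pool.X[i], lab)
        k += 1
    if not labeled.has_both_classes():
        raise SingleClassError("exhausted pool without observing both classes")
    return labeled


def initial_prevalence(labeled: LabeledSet) -> float:
    """p0 estimate: minority fraction observed in the bootstrap set."""
    return labeled.n_minority / len(labeled)


def run_strategy(pool: Pool, config: RunConfig, test_pool: Pool | None = None, oracle: AnnotationOracle | None = None) -> RunTrace:
    """Execute one training strategy end to end and record its trace.

    The pool must be disjoint from the test pool.  Pool exhaustion before
    T iterations truncates the trace (logged, not fatal).
    """
    if test_pool is not None and set(pool.ids) & set(test_pool.ids):
        raise ValidationError("train and test pools must be disjoint")
    oracle = oracle or AnnotationOracle.from_pool(pool)
    trace = RunTrace(config=config)

    if config.strategy == "full":
        labeled = LabeledSet()
        for i in range(len(pool)):
            labeled.add(pool.ids[i], pool.X[i], oracle.annotate(pool.ids[i], 0, "full"))
        acc, auc = _maybe_eval(labeled, test_pool, config.seed, 0)
        trace.records.append(_record(0, labeled, 0, 0, len(pool), len(pool), acc, auc))
        trace.training_set = labeled
        return trace

    labeled = bootstrap_init(pool, oracle, config.bootstrap_size, config.seed)
    trace.bootstrap_cost = oracle.calls
    unlabeled = {sid for sid in pool.ids} - set(labeled.ids)
    index_of = {sid: i for i, sid in enumerate(pool.ids)}
    query_rng = child_rng(config.seed, STREAM_QUERY)

    added1 = added2 = 0
    L = 0
    for t in range(1, config.T + 1):
        # candidate order is pool order restricted to unlabeled samples,
        # identical for AL (tau = 0.5) and RL modes by construction
        unlabeled_ids = [sid for sid in pool.ids if sid in unlabeled]
        if len(unlabeled_ids) < config.batch_size:
            logger.info("pool exhausted at iteration %d; truncating run", t)
            trace.truncated = True
            break

        if config.strategy in ("cbal", "ubal"):
            committee = train_committee(
                labeled.X, labeled.y, m=config.m, seed=child_seed(config.seed, STREAM_COMMITTEE, t),
                max_depth=config.max_depth,
            )
            trace.committee = committee
            mask = np.array([sid in unlabeled for sid in pool.ids])
            elig = find_eligible(committee, pool, config.tau, unlabeled_mask=mask)
            eligible_ids = list(elig.ids)
            if not eligible_ids:
                logger.info("empty eligible set at iteration %d; falling back to whole pool", t)
                eligible_ids = unlabeled_ids
        else:
            eligible_ids = unlabeled_ids

        try:
            if config.balanced:
                res = min_class_query(
                    eligible_ids, oracle, config.k1_hat, config.k2_hat, query_rng,
                    fallback_ids=unlabeled_ids, fallback=config.fallback, iteration=t,
                )
            else:
                res = random_query(
                    eligible_ids, oracle, config.batch_size, balanced=False, rng=query_rng, iteration=t,
                )
        except ExhaustionError as e:
            logger.info("quota exhaustion at iteration %d (%s); truncating run", t, e)
            trace.truncated = True
            if e.partial is not None:
                # partial batch: annotations were spent, keep them
                for sid, lab in zip(e.partial.batch_ids, e.partial.batch_labels):
                    labeled.add(sid, pool.X[index_of[sid]], lab)
                    if lab == MINORITY:
                        added1 += 1
                    else:
                        added2 += 1
                unlabeled -= set(e.partial.removed_ids)
                L += e.partial.n_annotated
                trace.records.append(
                    _record(t, labeled, added1, added2, e.partial.n_annotated, L, np.nan, np.nan)
                )
            break

        for sid, lab in zip(res.batch_ids, res.batch_labels):
            labeled.add(sid, pool.X[index_of[sid]], lab)
            if lab == MINORITY:
                added1 += 1
            else:
                added2 += 1
        unlabeled -= set(res.removed_ids)
        L += res.n_annotated

        do_eval = (config.eval_every > 0 and t % config.eval_every == 0) or t == config.T
        acc, auc = _maybe_eval(labeled, test_pool, config.seed, t) if do_eval else (np.nan, np.nan)
        trace.records.append(_record(t, labeled, added1, added2, res.n_annotated, L, acc, auc))

    trace.training_set = labeled
    return trace


def _record(t, labeled, added1, added2, n_t, L, acc, auc):
    return {
        "t": t,
        "n_minority": labeled.n_minority,
        "n_majority": labeled.n_majority,
        "added_minority": added1,
        "added_majority": added2,
        "N_t": int(n_t),
        "L": int(L),
        "accuracy": acc,
        "auc": auc,
    }


def _maybe_eval(labeled, test_pool, seed, t):
    if test_pool is None or not labeled.has_both_classes():
        return (np.nan, np.nan)
    res = evaluate_training_set(labeled.X, labeled.y, test_pool, seed=child_seed(seed, STREAM_EVAL, t))
    return (res.accuracy, res.auc)


def stopping_iteration(accuracies, delta: float) -> int:
    """Smallest t >= 1 with |A_t - A_{t-1}| <= delta; len(seq) if none.

    Training can stop once additional samples no longer change the
    evaluated accuracy by more than the similarity threshold delta.
    """
    accuracies = list(accuracies)
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    if len(accuracies) < 2:
        raise ValidationError("need at least two accuracy values")
    for t in range(1, len(accuracies)):
        if abs(accuracies[t] - accuracies[t - 1]) <= delta:
            return t
    return len(accuracies)


def compare_strategies(
    pool_spec: PoolSpec,
    configs: dict[str, RunConfig] | list[RunConfig],
    n_trials: int = 10,
    test_fraction: float = 1346 / 12588,
    seed: int = 0,
) -> pd.DataFrame:
    """Run several strategies across trials with per-trial train/test splits.

    Each trial re-splits the same generated dataset into train/test pools
    under a trial-specific seed, then runs every configuration against a
    fresh oracle.  Returns a tidy long-format table with one row per
    (trial, strategy, iteration).
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    if isinstance(configs, dict):
        configs = [replace(c, strategy=name) if c.strategy != name else c for name, c in configs.items()]
    dataset = make_feature_pool(pool_spec)
    frames = []
    for trial in range(n_trials):
        trial_seed = child_seed(seed, 500, trial)
        train, test = split_pool(dataset, test_fraction, seed=trial_seed)
        for cfg in configs:
            cfg_t = replace(cfg, seed=child_seed(trial_seed, 501))
            trace = run_strategy(train, cfg_t, test_pool=test)
            df = trace.to_frame()
            df.insert(0, "strategy", cfg.strategy)
            df.insert(0, "trial", trial)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def observed_balancing_costs(
    pool_spec: PoolSpec,
    k1_hat: int = 1,
    k2_hat: int = 1,
    T: int = 40,
    n_replicates: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical per-iteration balancing cost over seeded replicates.

    Runs class-balanced random querying (the whole unlabeled pool
    eligible, quotas enforced, surplus cached) for T iterations against a
    fresh oracle in each replicate, and records the annotations N_t each
    iteration actually consumed.  Returns a long-format table
    ``replicate, t, N_t`` — the empirical counterpart of
    :func:`cbal.cost_model.predict_cost_curve`.
    """
    pool = make_feature_pool(pool_spec)
    rows = []
    for rep in range(n_replicates):
        oracle = AnnotationOracle.from_pool(pool)
        rng = child_rng(seed, 700, rep)
        unlabeled = list(pool.ids)
        member = set(unlabeled)
        for t in range(1, T + 1):
            try:
                res = min_class_query(unlabeled, oracle, k1_hat, k2_hat, rng, fallback=False, iteration=t)
            except ExhaustionError:
                break
            removed = set(res.removed_ids)
            unlabeled = [sid for sid in unlabeled if sid not in removed]
            member -= removed
            rows.append({"replicate": rep, "t": t, "N_t": res.n_annotated})
    return pd.DataFrame(rows, columns=["replicate", "t", "N_t"])


def summarize_comparison(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and spread of the trace metrics per (strategy, iteration)."""
    return (
        table.groupby(["strategy", "t"])
        .agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_std=("accuracy", "std"),
            auc_mean=("auc", "mean"),
            auc_std=("auc", "std"),
            N_t_mean=("N_t", "mean"),
            N_t_std=("N_t", "std"),
            L_mean=("L", "mean"),
        )
        .reset_index()
    )
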