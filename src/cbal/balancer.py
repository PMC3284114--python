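"""Class-balanced annotation with true-cost metering.

The minority-class query loop annotates randomly drawn eligible samples
until per-class quotas (k1_hat minority, k2_hat majority) are met.  A
sample annotated while its class quota is already full is *surplus*: its
annotation cost has been spent, so it is parked in the oracle's cache and
consumed free of charge at later iterations.  The oracle counts every
distinct sample it labels exactly once — that count is the ground-truth
annotation cost the negative-binomial model predicts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import CbalError, ExhaustionError, ValidationError
from .pool import MAJORITY, MINORITY, Pool

logger = logging.getLogger(__name__)


class AnnotationOracle:
    """Simulated expert annotator over a pool's hidden labels.

    Charges one call per distinct sample ever labeled; surplus labels are
    cached per class and reused at no cost.  An attempt to charge the
    same sample twice is an accounting bug and raises.
    """

    def __init__(self, label_source: dict):
        self._labels = dict(label_source)
        self.calls = 0
        self.charged: set = set()
        self.cache: dict = {MINORITY: [], MAJORITY: []}
        self.audit: list = []  # (iteration, sample_id, class, charged, source)

    @classmethod
    def from_pool(cls, pool: Pool) -> "AnnotationOracle":
        return cls({sid: int(lab) for sid, lab in zip(pool.ids, pool.y)})

    def annotate(self, sample_id, iteration: int = -1, source: str = "eligible") -> int:
        """Reveal the true class of a sample, charging one oracle call."""
        if sample_id not in self._labels:
            raise ValidationError(f"unknown sample id {sample_id!r}")
        if sample_id in self.charged:
            raise CbalError(f"sample {sample_id!r} charged twice (accounting bug)")
        self.charged.add(sample_id)
        self.calls += 1
        label = self._labels[sample_id]
        self.audit.append((iteration, sample_id, label, 1, source))
        return label

    def peek_cached(self, label: int) -> bool:
        return bool(self.cache[label])

    def pop_cached(self, label: int, iteration: int = -1):
        sample_id = self.cache[label].pop(0)
        self.audit.append((iteration, sample_id, label, 0, "cache"))
        return sample_id

    def stash(self, sample_id, label: int) -> None:
        self.cache[label].append(sample_id)


@dataclass
class QueryResult:
    """Outcome of one balanced (or unbalanced) annotation round."""

    batch_ids: list = field(default_factory=list)
    batch_labels: list = field(default_factory=list)
    n_annotated: int = 0  # new oracle charges this round (N_t)
    surplus_used: int = 0  # quota slots filled from the cache
    fallback_triggered: bool = False
    annotated_ids: list = field(default_factory=list)  # everything charged this round

    @property
    def removed_ids(self) -> list:
        """Ids that must leave the unlabeled pool (batch + newly cached)."""
        return list(dict.fromkeys(self.batch_ids + self.annotated_ids))

    def class_counts(self) -> tuple[int, int]:
        n1 = sum(1 for v in self.batch_labels if v == MINORITY)
        return n1, len(self.batch_labels) - n1


def min_class_query(
    eligible_ids,
    oracle: AnnotationOracle,
    k1_hat: int,
    k2_hat: int,
    rng: np.random.Generator,
    fallback_ids=None,
    fallback: bool = True,
    iteration: int = -1,
) -> QueryResult:
    """Annotate random eligible samples until the class quotas are met.

    Cached surplus annotations are consumed first (free).  Fresh samples
    are drawn uniformly without replacement from ``eligible_ids``; a
    sample whose class quota is already full is cached for later rounds
    (cost already charged).  If the eligible set runs dry before the
    quotas fill and ``fallback`` is true, drawing continues from
    ``fallback_ids`` (the full unlabeled pool); otherwise an
    :class:`ExhaustionError` carries the partial batch.
    """
    if k1_hat + k2_hat <= 0:
        raise ValidationError("k1_hat + k2_hat must be > 0")
    res = QueryResult()
    need = {MINORITY: int(k1_hat), MAJORITY: int(k2_hat)}

    # 1. cache first — already-paid annotations fill quota slots for free
    for label in (MINORITY, MAJORITY):
        while need[label] > 0 and oracle.peek_cached(label):
            sid = oracle.pop_cached(label, iteration)
            res.batch_ids.append(sid)
            res.batch_labels.append(label)
            res.surplus_used += 1
            need[label] -= 1

    # 2. fresh draws without replacement from the eligible set
    def _draw_from(candidates, source):
        candidates = [s for s in candidates if s not in res.batch_ids and s not in res.annotated_ids]
        order = rng.permutation(len(candidates))
        for j in order:
            if need[MINORITY] == 0 and need[MAJORITY] == 0:
                return
            sid = candidates[j]
            label = oracle.annotate(sid, iteration, source)
            res.annotated_ids.append(sid)
            res.n_annotated += 1
            if need[label] > 0:
                res.batch_ids.append(sid)
                res.batch_labels.append(label)
                need[label] -= 1
            else:
                oracle.stash(sid, label)

    _draw_from(list(eligible_ids), "eligible")

    if (need[MINORITY] > 0 or need[MAJORITY] > 0) and fallback and fallback_ids is not None:
        remaining = [s for s in fallback_ids if s not in set(eligible_ids)]
        if remaining:
            res.fallback_triggered = True
            logger.info("eligible set exhausted at iteration %d; falling back to full pool", iteration)
            _draw_from(remaining, "fallback")

    if need[MINORITY] > 0 or need[MAJORITY] > 0:
        raise ExhaustionError(
            f"quotas unfillable: still need {need[MINORITY]} minority, {need[MAJORITY]} majority",
            partial=res,
            n_annotated=res.n_annotated,
        )
    return res


def random_query(
    pool_ids,
    oracle: AnnotationOracle,
    K: int,
    balanced: bool,
    k1_hat: int = 0,
    k2_hat: int = 0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    iteration: int = -1,
) -> QueryResult:
    """Random-learning annotation round.

    ``balanced=True`` delegates to :func:`min_class_query` with the whole
    pool eligible (class-balanced random learning); ``balanced=False``
    annotates the first K random samples regardless of class, so
    ``n_annotated`` is always K.
    """
    if K <= 0:
        raise ValidationError("K must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if balanced:
        return min_class_query(pool_ids, oracle, k1_hat, k2_hat, rng, fallback=False, iteration=iteration)
    pool_ids = list(pool_ids)
    if K > len(pool_ids):
        res = QueryResult()
        raise ExhaustionError(f"K={K} exceeds pool size {len(pool_ids)}", partial=res)
    res = QueryResult()
    order = rng.permutation(len(pool_ids))
    for j in order[:K]:
        sid = pool_ids[j]
        label = oracle.annotate(sid, iteration, "eligible")
        res.annotated_ids.append(sid)
        res.batch_ids.append(sid)
        res.batch_labels.append(label)
        res.n_annotated += 1
    return res


def write_audit_log(oracle: AnnotationOracle, path) -> None:
    """Stream the oracle's annotation events to a CSV audit log."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration", "sample_id", "class", "charged", "source"])
        w.writerows(oracle.audit)
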