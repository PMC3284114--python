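"""Query-by-committee learner.

A committee of M decision trees, each fit on an independent bootstrap
resample of the current labeled set (bagging), produces a fuzzy
confidence T(r) in [0, 1] for every sample: the fraction of members
voting for the minority class.  T = 1 means unanimous confidence the
sample is minority-class; T = 0 unanimous majority-class; T near 0.5
means the committee disagrees — the sample is informative.

The eligible (informative) set at confidence margin tau is
``{r : |T(r) - 0.5| <= tau}``: tau = 0.5 makes every sample eligible
(active learning degenerates to random learning), while tau = 0 keeps
only samples with perfect committee disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from ._rng import child_rng, child_seed
from .exceptions import SingleClassError, ValidationError
from .pool import MINORITY, Pool

DEFAULT_COMMITTEE_SIZE = 10


@dataclass
class Committee:
    """M bagged binary decision trees with a shared vote interface."""

    members: list
    m: int
    seed: int
    trained_on: int = 0  # size of the labeled set the committee saw

    def votes(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, m) matrix of member votes for the minority class."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.members[0].n_features_in_:
            raise ValidationError(
                f"feature dimension {X.shape[1]} does not match committee ({self.members[0].n_features_in_})"
            )
        return np.column_stack([(t.predict(X) == MINORITY).astype(float) for t in self.members])


def train_committee(X, y, m: int = DEFAULT_COMMITTEE_SIZE, seed: int = 0, max_depth: int | None = None) -> Committee:
    """Fit M trees on independent bootstrap resamples of the labeled set.

    Each member sees a resample (with replacement, same size as the
    labeled set) drawn under a per-member seed; resamples that miss a
    class are redrawn so every member is a two-class classifier.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if m < 2:
        raise ValidationError("committee size m must be >= 2")
    if len(np.unique(y)) < 2:
        raise SingleClassError(
            "labeled set contains a single class; extend the bootstrap sample until both classes are present"
        )
    n = len(y)
    members = []
    for j in range(m):
        rng = child_rng(seed, 10, j)
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        tree = DecisionTreeClassifier(max_depth=max_depth, random_state=child_seed(seed, 11, j))
        tree.fit(X[idx], y[idx])
        members.append(tree)
    return Committee(members=members, m=m, seed=seed, trained_on=n)


def confidence(committee: Committee, X) -> np.ndarray:
    """Fuzzy confidence T in [0, 1]: fraction of members voting minority.

    Values are on the grid {0, 1/M, ..., 1}.  Accepts a single feature
    vector or a matrix; returns a scalar array of matching length.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    T = committee.votes(np.atleast_2d(X)).mean(axis=1)
    return float(T[0]) if single else T


@dataclass
class EligibleSet:
    """The informative subset of an unlabeled pool at margin tau.

    ``k1``/``k2`` are the true minority/majority member counts — visible
    only to the simulation oracle, never to learners.
    """

    indices: np.ndarray  # positions within the queried pool
    ids: np.ndarray
    confidences: np.ndarray
    tau: float
    k1: int = 0
    k2: int = 0

    def __len__(self) -> int:
        return len(self.indices)


def find_eligible(committee: Committee, pool: Pool, tau: float, unlabeled_mask=None) -> EligibleSet:
    """Samples whose committee confidence lies within tau of 0.5.

    The inequality is inclusive, so tau = 0.5 returns the entire pool and
    tau = 0 returns only samples at exactly T = 0.5 (attainable only for
    even M).  An empty pool yields an empty eligible set.
    """
    if not 0.0 <= tau <= 0.5:
        raise ValidationError("tau must be in [0, 0.5]")
    if unlabeled_mask is None:
        unlabeled_mask = np.ones(len(pool), dtype=bool)
    cand = np.flatnonzero(unlabeled_mask)
    if len(cand) == 0:
        return EligibleSet(indices=cand, ids=pool.ids[cand], confidences=np.empty(0), tau=tau)
    T = confidence(committee, pool.X[cand])
    keep = np.abs(T - 0.5) <= tau + 1e-12
    idx = cand[keep]
    y_members = pool.y[idx]
    return EligibleSet(
        indices=idx,
        ids=pool.ids[idx],
        confidences=T[keep],
        tau=tau,
        k1=int((y_members == MINORITY).sum()),
        k2=int((y_members != MINORITY).sum()),
    )
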