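"""Training-set evaluation with a held-out probabilistic classifier.

To measure how good a training set is, a probabilistic scorer — a
boosted-tree ensemble, deliberately a different learner from the bagged
committee that drives sample selection — is fit on the training set and
applied to an independent test pool.  From the scores we build the ROC
curve by sweeping the decision threshold over every distinct score value
(plus the endpoints), integrate it for the AUC, place the operating
point at the Youden-J maximizer (ties broken toward the lower
threshold), and report accuracy at that threshold using the hard rule
``label = 1 iff score > theta`` (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier

from .exceptions import SingleClassError, ValidationError
from .pool import MINORITY


def fit_eval_classifier(X, y, seed: int = 0, n_estimators: int = 100):
    """Fit the evaluation scorer: sample -> P(minority class) in [0, 1].

    Deterministic under ``seed``.  Any probabilistic classifier could
    stand here; scores only need a calibrated *order* since evaluation
    sweeps all thresholds.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise SingleClassError("evaluation classifier needs both classes in the training set")
    clf = GradientBoostingClassifier(
        n_estimators=n_estimators, max_depth=2, learning_rate=0.5, random_state=seed
    )
    clf.fit(np.asarray(X, dtype=float), y)
    minority_col = int(np.flatnonzero(clf.classes_ == MINORITY)[0])

    def scorer(Xq):
        return clf.predict_proba(np.atleast_2d(np.asarray(Xq, dtype=float)))[:, minority_col]

    scorer.model = clf
    return scorer


def hard_label(score, theta: float):
    """Hard classification: 1 iff score > theta (strict), else 0."""
    score = np.asarray(score, dtype=float)
    if not 0.0 <= theta <= 1.0:
        raise ValidationError("theta must be in [0, 1]")
    if np.any((score < 0) | (score > 1)):
        raise ValidationError("scores must be in [0, 1]")
    out = (score > theta).astype(int)
    return int(out) if out.ndim == 0 else out


def accuracy(truth, predicted) -> float:
    """Fraction of agreements between true and predicted labels."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.size == 0:
        raise ValidationError("truth and predicted must be equal-length, non-empty")
    return float((truth == predicted).mean())


@dataclass
class EvalResult:
    """Scores, ROC curve, AUC, operating threshold and accuracy there."""

    scores: np.ndarray
    auc: float
    theta: float
    accuracy: float
    roc: np.ndarray = field(default=None, repr=False)  # (n_points, 2): FPR, TPR


def roc_and_auc(scores, truth) -> EvalResult:
    """ROC curve, trapezoidal AUC and Youden-J operating point.

    Sweeps the threshold over all distinct scores plus the endpoints
    {0, 1}; AUC is the trapezoidal integral of TPR over FPR (equal to the
    Mann-Whitney pairwise statistic, ties counted 1/2); theta* maximizes
    TPR - FPR, ties resolved toward the lower threshold; the reported
    accuracy applies the strict rule score > theta*.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if len(scores) != len(truth) or len(scores) == 0:
        raise ValidationError("scores and truth must be equal-length, non-empty")
    classes = np.unique(truth)
    if len(classes) < 2:
        raise ValidationError("AUC undefined: truth contains a single class")

    pos = truth == MINORITY
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    # descending thetas: predicted-positive sets grow, ROC walks (0,0) -> (1,1)
    thetas = np.unique(np.concatenate([[0.0, 1.0], np.clip(scores, 0.0, 1.0)]))[::-1]
    fpr = np.empty(len(thetas))
    tpr = np.empty(len(thetas))
    for i, th in enumerate(thetas):
        pred = scores > th
        tpr[i] = (pred & pos).sum() / n_pos
        fpr[i] = (pred & ~pos).sum() / n_neg
    if tpr[-1] < 1.0 or fpr[-1] < 1.0:  # scores at exactly 0 are never predicted positive
        thetas = np.append(thetas, 0.0)
        fpr = np.append(fpr, 1.0)
        tpr = np.append(tpr, 1.0)
    auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    theta = float(thetas[best[-1]])  # thetas descend: last tie index is the lowest theta
    acc = accuracy(truth, hard_label(np.clip(scores, 0.0, 1.0), theta))

    roc_pts = np.column_stack([fpr, tpr])
    return EvalResult(scores=scores, auc=auc, theta=theta, accuracy=acc, roc=roc_pts)


def evaluate_training_set(X_train, y_train, test_pool, seed: int = 0) -> EvalResult:
    """Fit the evaluation scorer on a training set and score a test pool."""
    scorer = fit_eval_classifier(X_train, y_train, seed=seed)
    scores = scorer(test_pool.X)
    return roc_and_auc(scores, test_pool.y)
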