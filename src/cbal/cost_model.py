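"""Negative-binomial model of class-balancing annotation cost.

When eligible samples are annotated uniformly at random and a fraction p
of them belong to the minority class, the number of annotations N needed
to observe k1_hat minority samples is a negative-binomial random
variable:

    P(N = n) = C(n-1, k1_hat-1) * p**k1_hat * (1-p)**(n-k1_hat)

The model predicts the per-iteration annotation cost either as the
distribution's P_delta-quantile (the smallest N such that the minority
quota is met within N annotations with probability >= P_delta) or as its
mean k1_hat / p, and tracks the drift of p across iterations: removing
the k1_hat annotated minority samples from a pool of k1 + k2 candidates
updates the minority-observation probability to

    p_next = (k1 - k1_hat) / (k1 + k2 - N).

Summing the per-iteration costs gives the total training cost L.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ModelInconsistencyError, UndefinedProbabilityError, ValidationError

logger = logging.getLogger(__name__)


def _check_p(p: float) -> float:
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"probability p={p} outside [0, 1]")
    return float(p)


def negbin_prob(k1_hat: int, n: int, p: float) -> float:
    """P(the k1_hat-th minority sample is observed exactly on annotation n).

    Zero for n < k1_hat.  With p = 1 the entire mass sits at n = k1_hat.
    """
    p = _check_p(p)
    if k1_hat < 1:
        raise ValidationError("k1_hat must be >= 1")
    if n < k1_hat:
        return 0.0
    if p == 0.0:
        return 0.0
    # scipy's nbinom counts failures before the k1_hat-th success
    return float(stats.nbinom.pmf(n - k1_hat, k1_hat, p))


def negbin_cdf(k1_hat: int, n: int, p: float) -> float:
    """P(at least k1_hat minority samples within n annotations)."""
    p = _check_p(p)
    if k1_hat < 1:
        raise ValidationError("k1_hat must be >= 1")
    if n < k1_hat or p == 0.0:
        return 0.0
    return float(stats.nbinom.cdf(n - k1_hat, k1_hat, p))


def expected_annotations(p: float, k1_hat: int) -> float:
    """Mean annotations until k1_hat minority observations: k1_hat / p."""
    p = _check_p(p)
    if p == 0.0:
        return float("inf")
    return k1_hat / p


def predict_annotations(
    p: float,
    k1_hat: int,
    p_delta: float = 0.95,
    pool_size: int = 10**9,
    mode: str = "quantile",
) -> int:
    """Predicted annotations N until the minority quota is met.

    mode="quantile" (default): smallest N with
    P(>= k1_hat minority within N) >= p_delta — the confidence-level
    reading of the model.  mode="as_printed": the N in
    [k1_hat, pool_size] whose pmf is closest to p_delta (smallest N on
    ties) — the literal minimization form.  The result is clamped to
    [k1_hat, pool_size]; p = 0 returns pool_size with a warning.
    """
    p = _check_p(p)
    if not 0.0 < p_delta < 1.0:
        raise ValidationError("p_delta must be in (0, 1)")
    if k1_hat < 1:
        raise ValidationError("k1_hat must be >= 1")
    if pool_size < k1_hat:
        raise ValidationError(f"pool_size {pool_size} cannot supply {k1_hat} minority samples")
    if p == 0.0:
        logger.warning("p = 0: minority class unobservable; predicting full-pool annotation")
        return int(pool_size)
    if mode == "quantile":
        n = k1_hat + int(stats.nbinom.ppf(p_delta, k1_hat, p))
    elif mode == "as_printed":
        xs = np.arange(k1_hat, pool_size + 1)
        pmf = stats.nbinom.pmf(xs - k1_hat, k1_hat, p)
        n = int(xs[np.argmin(np.abs(p_delta - pmf))])
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return int(min(max(n, k1_hat), pool_size))


def update_probability(k1_t: int, k2_t: int, k1_hat: int, n_t: int) -> float:
    """Minority-observation probability after one balanced iteration.

    From a candidate set with k1_t minority and k2_t majority samples,
    n_t were annotated, k1_hat of them minority; the remaining pool has
    minority fraction (k1_t - k1_hat) / (k1_t + k2_t - n_t).  Undefined
    (raises) when no samples remain; 0 when no minority samples remain.
    """
    denom = k1_t + k2_t - n_t
    if denom <= 0:
        raise UndefinedProbabilityError(
            "no samples remain in the pool; the updated probability is undefined"
        )
    if k1_t < k1_hat:
        raise ModelInconsistencyError(
            f"cannot have annotated {k1_hat} minority samples from a set holding {k1_t}"
        )
    p = (k1_t - k1_hat) / denom
    if not 0.0 <= p <= 1.0:
        raise ModelInconsistencyError(f"updated probability {p} outside [0, 1]")
    return float(p)


def total_cost(trace) -> int:
    """Total training cost L: the sum of per-iteration annotation counts."""
    trace = list(trace)
    if any(n < 0 for n in trace):
        raise ValidationError("annotation counts must be >= 0")
    return int(sum(trace))


def predict_cost_curve(
    p0: float,
    k1_hat: int,
    k2_hat: int,
    p_delta: float = 0.95,
    T: int = 40,
    pool_size: int = 11242,
    statistic: str = "quantile",
    update_source: str = "oracle_counts",
) -> pd.DataFrame:
    """Per-iteration predicted annotation costs for a whole training run.

    Iterates the single-step prediction and the probability update for
    t = 1..T.  ``update_source="oracle_counts"`` tracks exact integer
    class counts (simulation mode, ground truth known);
    ``"running_estimate"`` tracks only the estimated prevalence and pool
    size (deployment mode: class counts are estimated as p*|pool| before
    the update).  The two coincide when p0*pool_size is an integer.

    ``statistic`` selects the per-iteration prediction: "quantile" or
    "as_printed" (see :func:`predict_annotations`) or "mean"
    (k1_hat / p).  Every prediction is floored at the batch size
    k1_hat + k2_hat — an iteration must annotate at least its quota when
    no surplus cache exists — and capped at the remaining pool size.

    Returns a DataFrame with columns ``t, p_t, predicted_N_t, cumulative_L``.
    """
    _check_p(p0)
    if T < 1:
        raise ValidationError("T must be >= 1")
    if update_source not in ("oracle_counts", "running_estimate"):
        raise ValidationError(f"unknown update_source {update_source!r}")
    K = k1_hat + k2_hat
    if K <= 0:
        raise ValidationError("k1_hat + k2_hat must be > 0")

    k1 = p0 * pool_size
    if update_source == "oracle_counts":
        k1 = round(k1)
    total = float(pool_size)
    p = p0
    rows = []
    L = 0.0
    for t in range(1, T + 1):
        if total < K or k1 < k1_hat:
            logger.info("pool exhausted at iteration %d; truncating predicted curve", t)
            break
        if statistic == "mean":
            pred = expected_annotations(p, k1_hat) if p > 0 else total
        else:
            pred = predict_annotations(p, k1_hat, p_delta, pool_size=max(int(total), k1_hat), mode=statistic)
        pred = float(min(max(pred, K), total))
        L += pred
        rows.append({"t": t, "p_t": p, "predicted_N_t": pred, "cumulative_L": L})
        # advance the pool state by the predicted annotations
        new_total = total - pred
        new_k1 = k1 - k1_hat
        if new_total <= 0:
            break
        p = max(0.0, min(1.0, new_k1 / new_total))
        k1, total = new_k1, new_total
    return pd.DataFrame(rows, columns=["t", "p_t", "predicted_N_t", "cumulative_L"])
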