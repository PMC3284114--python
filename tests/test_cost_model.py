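"""Negative-binomial cost model against enumeration, closed forms and Monte Carlo."""

import itertools

import numpy as np
import pytest

from cbal.cost_model import (
    expected_annotations,
    negbin_cdf,
    negbin_prob,
    predict_annotations,
    predict_cost_curve,
    total_cost,
    update_probability,
)
from cbal.exceptions import ModelInconsistencyError, UndefinedProbabilityError, ValidationError


def enumerate_negbin(k1_hat, n, p):
    """Brute force: sum over all length-n annotation sequences whose n-th
    draw is the k1_hat-th minority observation."""
    total = 0.0
    for seq in itertools.product((0, 1), repeat=n):
        if seq[-1] == 1 and sum(seq) == k1_hat:
            s = sum(seq)
            total += p**s * (1 - p) ** (n - s)
    return total


class TestPmf:
    def test_first_draw_success(self):
        assert negbin_prob(1, 1, 0.25) == pytest.approx(0.25)

    def test_certain_success_mass_at_k(self):
        for k in (1, 2, 5):
            assert negbin_prob(k, k, 1.0) == pytest.approx(1.0)
            assert negbin_prob(k, k + 1, 1.0) == pytest.approx(0.0)

    def test_zero_below_k(self):
        assert negbin_prob(3, 2, 0.5) == 0.0

    @pytest.mark.parametrize("n", range(2, 13))
    def test_matches_exhaustive_enumeration(self, n):
        assert negbin_prob(2, n, 0.3) == pytest.approx(enumerate_negbin(2, n, 0.3), abs=1e-12)

    def test_cdf_matches_pmf_partial_sum(self):
        want = sum(negbin_prob(2, n, 0.3) for n in range(2, 9))
        assert negbin_cdf(2, 8, 0.3) == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("p,k", [(0.04, 1), (0.3, 2), (0.5, 5)])
    def test_pmf_sums_to_one(self, p, k):
        horizon = k + int(50 / p)
        total = sum(negbin_prob(k, n, p) for n in range(k, horizon))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_p_validation(self):
        with pytest.raises(ValidationError):
            negbin_prob(1, 1, 1.5)


class TestPredictAnnotations:
    def test_certain_success_lower_bound(self):
        assert predict_annotations(1.0, 3, 0.99) == 3

    def test_closed_form_k1(self):
        """k=1: smallest N with 1-(1-p)^N >= P_delta, i.e. ceil(ln(1-PD)/ln(1-p))."""
        for p in (0.01, 0.04, 0.1, 0.3, 0.5):
            for pd_ in (0.5, 0.9, 0.95, 0.99):
                want = int(np.ceil(np.log(1 - pd_) / np.log(1 - p)))
                assert predict_annotations(p, 1, pd_) == want

    def test_study_prevalence_value(self):
        assert predict_annotations(0.04, 1, 0.95) == 74

    @pytest.mark.parametrize("k", [2, 5])
    def test_monte_carlo_quantile(self, k):
        """Empirical P_delta-quantile of draws-until-k-successes within +/-1."""
        rng = np.random.default_rng(12345)
        for p, pd_ in [(0.1, 0.9), (0.3, 0.95)]:
            draws = rng.geometric(p, size=(100_000, k)).sum(axis=1)
            emp = int(np.quantile(draws, pd_, method="inverted_cdf"))
            assert abs(predict_annotations(p, k, pd_) - emp) <= 1

    def test_bounds_respected(self):
        assert predict_annotations(0.001, 1, 0.99, pool_size=50) == 50
        assert predict_annotations(0.9, 4, 0.5, pool_size=100) >= 4

    def test_zero_prevalence_full_pool(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="cbal.cost_model"):
            assert predict_annotations(0.0, 1, 0.95, pool_size=123) == 123
        assert any("unobservable" in r.message for r in caplog.records)

    def test_as_printed_mode(self):
        # with p=1 the pmf is 1 at N=k and 0 elsewhere; argmin |P_delta - pmf| is k
        assert predict_annotations(1.0, 2, 0.95, pool_size=10, mode="as_printed") == 2
        # smallest-x tie-break: symmetric pmf values resolve to the smaller N
        n = predict_annotations(0.5, 1, 0.95, pool_size=100, mode="as_printed")
        assert n == 1  # pmf(1)=0.5 is closest to 0.95

    def test_monotonicity(self):
        grid_p = [0.02, 0.05, 0.1, 0.3]
        for a, b in zip(grid_p, grid_p[1:]):
            assert predict_annotations(a, 2, 0.9) >= predict_annotations(b, 2, 0.9)
        for k in (1, 2, 4):
            assert predict_annotations(0.1, k + 1, 0.9) >= predict_annotations(0.1, k, 0.9)
        assert predict_annotations(0.1, 2, 0.99) >= predict_annotations(0.1, 2, 0.9)

    def test_infeasible_pool(self):
        with pytest.raises(ValidationError):
            predict_annotations(0.5, 5, 0.9, pool_size=3)


class TestUpdateProbability:
    def test_direct_substitution(self):
        assert update_probability(10, 90, 5, 50) == pytest.approx(0.1)

    def test_exhausted_minority(self):
        assert update_probability(5, 90, 5, 20) == 0.0

    def test_empty_pool_undefined(self):
        with pytest.raises(UndefinedProbabilityError):
            update_probability(10, 90, 5, 100)

    def test_inconsistency_detected(self):
        with pytest.raises(ModelInconsistencyError):
            update_probability(3, 90, 5, 20)


class TestTotalCost:
    def test_sum_and_empty(self):
        assert total_cost([2, 2, 2]) == 6
        assert total_cost([]) == 0

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            total_cost([2, -1])


class TestCostCurve:
    def test_certain_balance_predicts_batch_size(self):
        curve = predict_cost_curve(1.0, 1, 1, T=5, pool_size=1000, statistic="mean")
        assert (curve["predicted_N_t"] == 2).all()

    def test_near_constant_on_huge_pool(self):
        curve = predict_cost_curve(0.04, 1, 0, T=10, pool_size=10**6, statistic="quantile")
        assert curve["predicted_N_t"].nunique() == 1
        assert curve["predicted_N_t"].iloc[0] == 74

    def test_high_minority_quota_costs_more(self):
        """80% minority quota dominates 20% at every iteration (K=10)."""
        hi = predict_cost_curve(0.04, 8, 2, T=15, pool_size=11242, statistic="quantile")
        lo = predict_cost_curve(0.04, 2, 8, T=15, pool_size=11242, statistic="quantile")
        n = min(len(hi), len(lo))
        assert (hi["predicted_N_t"].to_numpy()[:n] >= lo["predicted_N_t"].to_numpy()[:n]).all()

    def test_cumulative_cost_is_running_sum(self):
        curve = predict_cost_curve(0.1, 1, 1, T=8, pool_size=5000, statistic="mean")
        assert np.allclose(curve["cumulative_L"], curve["predicted_N_t"].cumsum())

    def test_oracle_counts_vs_running_estimate_agree_on_integer_start(self):
        a = predict_cost_curve(0.04, 1, 1, T=10, pool_size=10000, update_source="oracle_counts")
        b = predict_cost_curve(0.04, 1, 1, T=10, pool_size=10000, update_source="running_estimate")
        assert np.allclose(a["predicted_N_t"], b["predicted_N_t"])

    def test_mean_cost_recovery_from_simulation(self, small_pool):
        """Mean simulated balancing cost ~ k1_hat/p within the 99% CI."""
        from cbal.balancer import AnnotationOracle, min_class_query

        p = small_pool.n_minority / len(small_pool)
        costs = []
        for seed in range(300):
            o = AnnotationOracle.from_pool(small_pool)
            res = min_class_query(list(small_pool.ids), o, 1, 0, np.random.default_rng(seed))
            costs.append(res.n_annotated)
        ci = 2.576 * np.std(costs) / np.sqrt(len(costs))
        assert abs(np.mean(costs) - expected_annotations(p, 1)) <= ci + 0.5
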