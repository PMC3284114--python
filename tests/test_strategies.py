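"""Training strategies: bootstrap, traces, balance invariants, stopping rule."""

import numpy as np
import pytest

from cbal import PoolSpec, RunConfig, make_feature_pool, run_strategy, split_pool
from cbal.balancer import AnnotationOracle
from cbal.strategies import (
    bootstrap_init,
    compare_strategies,
    initial_prevalence,
    observed_balancing_costs,
    stopping_iteration,
    summarize_comparison,
)
from cbal.exceptions import SingleClassError, ValidationError


class TestBootstrap:
    def test_both_classes_present(self, small_pool, oracle):
        labeled = bootstrap_init(small_pool, oracle, size=10, seed=1)
        assert len(labeled) >= 10
        assert labeled.has_both_classes()

    def test_cost_charged_per_draw(self, small_pool, oracle):
        labeled = bootstrap_init(small_pool, oracle, size=10, seed=2)
        assert oracle.calls == len(labeled)

    def test_p0_estimate_is_bootstrap_minority_fraction(self, small_pool, oracle):
        labeled = bootstrap_init(small_pool, oracle, size=25, seed=3)
        assert initial_prevalence(labeled) == labeled.n_minority / len(labeled)

    def test_single_class_pool_fails(self):
        pool = make_feature_pool(PoolSpec(n_total=50, minority_fraction=0.1, dim=2, seed=1)).subset(
            np.arange(10)
        )
        pool.y[:] = 0
        with pytest.raises(SingleClassError):
            bootstrap_init(pool, AnnotationOracle.from_pool(pool), 5, 1)


class TestRunStrategy:
    @pytest.mark.parametrize("strategy", ["cbal", "cbrl"])
    def test_balanced_growth_and_exact_balance(self, small_pool, strategy):
        cfg = RunConfig(strategy=strategy, T=8, tau=0.25, k1_hat=1, k2_hat=1, seed=4, eval_every=0)
        oracle = AnnotationOracle.from_pool(small_pool)
        trace = run_strategy(small_pool, cfg, oracle=oracle)
        for rec in trace.records:
            t = rec["t"]
            assert rec["added_minority"] == t * cfg.k1_hat
            assert rec["added_majority"] == t * cfg.k2_hat
        # training set = bootstrap + t * (k1_hat + k2_hat)
        assert len(trace.training_set) == trace.bootstrap_cost + 8 * 2
        # cost conservation: oracle calls = bootstrap + sum N_t
        assert oracle.calls == trace.bootstrap_cost + sum(r["N_t"] for r in trace.records)

    def test_training_set_and_pool_disjoint(self, small_pool):
        cfg = RunConfig(strategy="cbal", T=5, seed=5, eval_every=0)
        oracle = AnnotationOracle.from_pool(small_pool)
        trace = run_strategy(small_pool, cfg, oracle=oracle)
        # every id annotated exactly once, none duplicated in the training set
        assert len(set(trace.training_set.ids)) == len(trace.training_set.ids)
        assert set(trace.training_set.ids) <= set(small_pool.ids)

    def test_unbalanced_costs_exactly_K(self, small_pool):
        cfg = RunConfig(strategy="ubrl", T=6, K=2, seed=6, eval_every=0)
        trace = run_strategy(small_pool, cfg)
        assert all(r["N_t"] == 2 for r in trace.records)
        assert trace.records[-1]["L"] == 12

    def test_full_uses_entire_pool(self, small_pool):
        trace = run_strategy(small_pool, RunConfig(strategy="full", seed=1))
        assert len(trace.training_set) == len(small_pool)
        assert trace.records[0]["N_t"] == len(small_pool)

    def test_tau_half_equals_balanced_random(self, small_pool):
        a = run_strategy(small_pool, RunConfig(strategy="cbal", T=6, tau=0.5, seed=7, eval_every=0))
        b = run_strategy(small_pool, RunConfig(strategy="cbrl", T=6, tau=0.5, seed=7, eval_every=0))
        assert a.training_set.ids == b.training_set.ids
        assert [r["N_t"] for r in a.records] == [r["N_t"] for r in b.records]

    def test_end_to_end_determinism(self, small_pool):
        cfg = RunConfig(strategy="cbal", T=5, seed=8, eval_every=0)
        a, b = run_strategy(small_pool, cfg), run_strategy(small_pool, cfg)
        assert a.training_set.ids == b.training_set.ids
        assert a.to_frame().equals(b.to_frame())

    def test_exhaustion_truncates_with_consistent_accounting(self):
        pool = make_feature_pool(PoolSpec(n_total=60, minority_fraction=0.1, dim=2, seed=9))
        cfg = RunConfig(strategy="cbrl", T=100, k1_hat=1, k2_hat=1, seed=9, eval_every=0)
        oracle = AnnotationOracle.from_pool(pool)
        trace = run_strategy(pool, cfg, oracle=oracle)
        assert trace.truncated
        assert len(trace.records) < 100
        assert oracle.calls == trace.bootstrap_cost + sum(r["N_t"] for r in trace.records)

    def test_overlapping_test_pool_rejected(self, small_pool):
        with pytest.raises(ValidationError):
            run_strategy(small_pool, RunConfig(strategy="cbrl", T=2), test_pool=small_pool)

    def test_evaluation_recorded(self, small_pool):
        train, test = split_pool(small_pool, 0.25, seed=10)
        trace = run_strategy(train, RunConfig(strategy="cbal", T=3, seed=10, eval_every=1), test_pool=test)
        df = trace.to_frame()
        assert df["auc"].notna().all()
        assert df["auc"].between(0, 1).all() and df["accuracy"].between(0, 1).all()


class TestStopping:
    def test_direct_evaluation(self):
        assert stopping_iteration([0.50, 0.70, 0.71], 0.02) == 2

    def test_constant_sequence(self):
        assert stopping_iteration([0.8, 0.8, 0.8], 0.0) == 1

    def test_never_satisfied_returns_length(self):
        assert stopping_iteration([0.1, 0.3, 0.5, 0.7], 0.1) == 4

    def test_short_sequences_invalid(self):
        with pytest.raises(ValidationError):
            stopping_iteration([0.5], 0.1)


@pytest.fixture(scope="module")
def table():
    spec = PoolSpec(n_total=800, minority_fraction=0.05, class_separation=2.0, dim=4, seed=11)
    cfgs = [
        RunConfig(strategy="cbal", T=4, seed=0, eval_every=0),
        RunConfig(strategy="ubrl", T=4, K=2, seed=0, eval_every=0),
        RunConfig(strategy="full", T=4, seed=0),
    ]
    return compare_strategies(spec, cfgs, n_trials=3, test_fraction=0.2, seed=12)


class TestCompare:
    def test_rows_per_trial_and_strategy(self, table):
        cbal_rows = table[(table.strategy == "cbal")]
        assert set(cbal_rows["trial"]) == {0, 1, 2}
        assert len(cbal_rows) == 3 * 4

    def test_full_constant_across_iterations(self, table):
        full = table[table.strategy == "full"]
        for trial, grp in full.groupby("trial"):
            assert grp["auc"].nunique() == 1
            assert grp["L"].nunique() == 1

    def test_summary_shape(self, table):
        summary = summarize_comparison(table)
        assert {"strategy", "t", "auc_mean", "N_t_mean"} <= set(summary.columns)


def test_ratio_sweep_cost_ordering():
    """Higher minority quotas cost more annotations per iteration."""
    spec = PoolSpec(n_total=3000, minority_fraction=0.04, class_separation=1.0, dim=2, seed=13)
    hi = observed_balancing_costs(spec, 8, 2, T=5, n_replicates=8, seed=14)
    lo = observed_balancing_costs(spec, 2, 8, T=5, n_replicates=8, seed=14)
    assert hi["N_t"].mean() > lo["N_t"].mean()
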