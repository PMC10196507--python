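"""Bootstrap decisions, percentile CIs, and the graph-inference pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from binscm.data import BinaryDataset, bootstrap_resample
from binscm.exceptions import DegenerateColumnError
from binscm.inference import (
    _Moments,
    bootstrap_distribution,
    confounding_filter,
    infer_association_graph,
    infer_causal_graph,
    orient_edges,
    percentile_ci,
)
from binscm.inference import test_nonzero as decide_nonzero
from binscm.simulator import BSCMModel, benchmark_model, benchmark_true_edges, simulate_bscm

from conftest import table_dataset


class TestPercentileCI:
    def test_constant_samples_give_point_interval(self):
        assert percentile_ci([2.0] * 10) == (2.0, 2.0)

    def test_linear_interpolation_between_order_statistics(self):
        lo, hi = percentile_ci(np.arange(1, 101, dtype=float), level=0.95)
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_fewer_than_two_samples_is_an_error(self):
        with pytest.raises(ValueError):
            percentile_ci([1.0])


class TestTestNonzero:
    @pytest.mark.parametrize("method", ["rank-zero", "percentile"])
    def test_all_zero_samples_never_reject(self, method):
        dec = decide_nonzero([0.0] * 50, "greater", 0.05, method=method)
        assert dec.p_value == 1.0
        assert not dec.reject

    def test_constant_positive_samples_reject_one_sided_rank(self):
        dec = decide_nonzero([0.2] * 100, "greater", 0.05, method="rank-zero")
        assert dec.reject

    @pytest.mark.parametrize("method", ["rank-zero", "percentile"])
    def test_samples_symmetric_about_zero_fail_two_sided(self, method):
        samples = [0.1, -0.1] * 50
        dec = decide_nonzero(samples, "two-sided", 0.05, method=method)
        assert not dec.reject

    def test_sign_consistent_samples_with_zero_atom_reject(self):
        # nonnegative statistic with bootstrap mass at exactly zero:
        # one-sided concentration, not a straddle
        samples = [0.0] * 5 + [0.03] * 95
        dec = decide_nonzero(samples, "two-sided", 0.05, method="percentile")
        assert dec.reject

    def test_reject_iff_p_below_alpha_and_ci_is_ordered(self, rng):
        samples = rng.normal(0.1, 0.05, size=100)
        dec = decide_nonzero(samples, "two-sided", 0.05)
        assert dec.reject == (dec.p_value < 0.05)
        assert dec.ci[0] <= dec.ci[1]
        assert samples.min() <= dec.ci[0] and dec.ci[1] <= samples.max()


class TestBootstrapDistribution:
    def test_single_row_source_yields_constant_samples(self):
        ds = BinaryDataset(np.array([[1, 1]]), ("a", "b"))
        ens = bootstrap_resample(ds, q=3, seed=0)
        samples = bootstrap_distribution(ens, "dependency", 0, 1)
        assert samples == [0.0, 0.0, 0.0]

    def test_fixed_seed_gives_identical_sample_vector(self):
        ds = table_dataset(30, 10, 10, 30)
        s1 = bootstrap_distribution(bootstrap_resample(ds, 20, seed=5),
                                    "odd_diff", 0, 1)
        s2 = bootstrap_distribution(bootstrap_resample(ds, 20, seed=5),
                                    "odd_diff", 0, 1)
        assert s1 == s2

    def test_loop_route_matches_vectorized_moments_route(self):
        # dual route: the per-replicate estimator path must agree with the
        # matrix-product path used by the pipeline
        ds = table_dataset(22, 13, 9, 31)
        ens = bootstrap_resample(ds, q=25, seed=8)
        mom = _Moments(ens)
        loop = bootstrap_distribution(ens, "odd_diff", 0, 1)
        assert np.allclose(loop, mom.cov_samples(0, 1), atol=1e-12)
        loop_dep = bootstrap_distribution(ens, "dependency", 0, 1)
        assert np.allclose(loop_dep, np.abs(mom.cov_samples(0, 1)), atol=1e-12)

    def test_mean_of_odd_diff_on_independent_columns_is_near_zero(self, rng):
        X = (rng.random((800, 2)) < 0.5).astype(int)
        ds = BinaryDataset(X, ("a", "b"))
        ens = bootstrap_resample(ds, q=100, seed=1)
        samples = np.array(bootstrap_distribution(ens, "odd_diff", 0, 1))
        assert abs(samples.mean()) < 3 * samples.std() / np.sqrt(len(samples)) + 3 * 0.5 / np.sqrt(800)


class TestAssociationGraph:
    def test_direct_benchmark_relations_are_candidates(self):
        ds = simulate_bscm(benchmark_model(0.3), 500, seed=4)
        ens = bootstrap_resample(ds, q=100, seed=9)
        pairs = {e.pair for e in infer_association_graph(ens, 0.05)}
        required = {(0, 1), (0, 2), (1, 3), (3, 4), (0, 5), (3, 5)}
        assert {tuple(sorted(p)) for p in pairs} >= required

    def test_identical_columns_form_an_edge(self):
        col = np.array([0, 1] * 25)
        ds = BinaryDataset(np.column_stack([col, col]), ("a", "b"))
        ens = bootstrap_resample(ds, q=50, seed=2)
        assert {e.pair for e in infer_association_graph(ens, 0.05)} == {(0, 1)}


class TestConfoundingFilter:
    @pytest.mark.parametrize(
        "parents, label",
        [(((), (0,), (1,)), "chain"), (((1,), (), (1,)), "confounder")],
    )
    def test_screened_pair_is_removed(self, parents, label):
        model = BSCMModel(("X", "Z", "Y"), parents, 0.3)
        ds = simulate_bscm(model, 2000, seed=13)
        ens = bootstrap_resample(ds, q=100, seed=14)
        mom = _Moments(ens)
        cands = infer_association_graph(ens, 0.05, moments=mom)
        assert (0, 2) in {e.pair for e in cands}, "X-Y must start as candidate"
        kept, removed = confounding_filter(ens, cands, 0.05, moments=mom)
        assert (0, 2) in removed
        assert "Z" in removed[(0, 2)]

    def test_direct_parent_edge_survives_every_screen(self):
        ds = simulate_bscm(benchmark_model(0.3), 500, seed=4)
        ens = bootstrap_resample(ds, q=100, seed=9)
        mom = _Moments(ens)
        cands = infer_association_graph(ens, 0.05, moments=mom)
        kept, removed = confounding_filter(ens, cands, 0.05, moments=mom)
        assert (0, 5) not in removed  # X1 - X6 is a direct gate input
        assert (0, 5) in {e.pair for e in kept}


class TestOrientEdges:
    def test_benchmark_gate_edge_is_oriented_into_the_child(self):
        ds = simulate_bscm(benchmark_model(0.3), 500, seed=4)
        ens = bootstrap_resample(ds, q=100, seed=9)
        mom = _Moments(ens)
        cands = infer_association_graph(ens, 0.05, moments=mom)
        kept, _ = confounding_filter(ens, cands, 0.05, moments=mom)
        graph = orient_edges(ens, kept, 0.05, moments=mom)
        assert (0, 5) in graph.directed_edges()  # X1 -> X6

    def test_symmetric_joint_with_equal_marginals_stays_undirected(self):
        col = np.array([0, 1] * 30)
        ds = BinaryDataset(np.column_stack([col, col]), ("a", "b"))
        ens = bootstrap_resample(ds, q=60, seed=3)
        mom = _Moments(ens)
        cands = infer_association_graph(ens, 0.05, moments=mom)
        graph = orient_edges(ens, cands, 0.05, moments=mom)
        assert graph.directed_edges() == set()
        assert graph.undirected_pairs() == {frozenset({0, 1})}


class TestFullPipeline:
    def test_pipeline_is_monotone_and_deterministic(self):
        ds = simulate_bscm(benchmark_model(0.3), 300, seed=21)
        r1 = infer_causal_graph(ds, q=60, alpha=0.05, seed=5)
        r2 = infer_causal_graph(ds, q=60, alpha=0.05, seed=5)
        # determinism
        assert r1.report == r2.report
        # monotonicity: oriented pairs <= filtered pairs <= candidates
        cand_pairs = {e.pair for e in r1.candidates}
        final_pairs = {e.pair for e in r1.graph.edges}
        assert final_pairs <= cand_pairs
        assert final_pairs == cand_pairs - set(r1.removed)

    def test_report_carries_all_decisions_per_pair(self):
        ds = simulate_bscm(benchmark_model(0.3), 300, seed=21)
        report = infer_causal_graph(ds, q=60, alpha=0.05, seed=5).report
        assert set(report) >= {"n", "d", "q", "alpha", "seed", "names",
                               "pairs", "edges", "removed_by_confounding"}
        for rec in report["edges"]:
            assert rec["dep"]["reject"] and rec["odd"]["reject"]
            if rec["status"] == "directed":
                assert rec["dir"]["reject"]
                assert rec["effect_given_cause"]["mean"] >= 0

    def test_all_degenerate_dataset_is_an_error(self):
        ds = BinaryDataset(np.array([[1, 0]]), ("a", "b"))
        with pytest.raises(DegenerateColumnError):
            infer_causal_graph(ds, q=5, alpha=0.05, seed=0)

    def test_moderate_dimension_smoke(self):
        # d=12 variables, pure noise plus one gate; completes quickly and
        # examines every pair once
        names = tuple(f"V{k}" for k in range(12))
        parents = [()] * 12
        parents[0] = (1, 2)
        model = BSCMModel(names, tuple(parents), 0.3)
        ds = simulate_bscm(model, 300, seed=2)
        res = infer_causal_graph(ds, q=30, alpha=0.05, seed=3)
        assert res.report["d"] == 12
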