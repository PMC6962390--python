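"""Train/probe split, AUC tallies, repeated runs, alpha sweep."""

import math

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from ccpalink.evaluation import (
    DEFAULT_ALPHA_GRID,
    AUCEstimate,
    EvaluationError,
    TrainProbeSplit,
    alpha_sweep,
    auc_from_scores,
    derive_seed,
    estimate_auc,
    run_experiment,
    split_train_probe,
)
from ccpalink.graph import canonical_pair
from ccpalink.synthetic import planted_benchmark
from conftest import seeded_er_graphs


def planted_split(n=60, fraction=0.25, seed=5):
    net, future = planted_benchmark(n, fraction, seed)
    return TrainProbeSplit(net, future, 1 - fraction, seed)


class TestSeedDerivation:
    def test_stable_distinct_and_bounded(self):
        seeds = [derive_seed(7, i) for i in range(1000)]
        assert seeds == [derive_seed(7, i) for i in range(1000)]
        assert len(set(seeds)) == 1000
        assert all(0 <= s < 2**31 for s in seeds)
        assert derive_seed(8, 0) != derive_seed(7, 0)


class TestSplit:
    def test_80_20_on_ten_edges(self):
        net = nx.cycle_graph(10)
        split = split_train_probe(net, 0.8, seed=3)
        assert split.training.number_of_edges() == 8
        assert len(split.probe_edges) == 2

    def test_same_seed_same_split(self):
        net = nx.gnp_random_graph(20, 0.2, seed=9)
        a = split_train_probe(net, 0.8, seed=11)
        b = split_train_probe(net, 0.8, seed=11)
        assert a.probe_edges == b.probe_edges
        assert set(a.training.edges) == set(b.training.edges)

    def test_parameter_errors(self):
        net = nx.cycle_graph(5)
        with pytest.raises(ValueError):
            split_train_probe(net, 1.2, seed=0)
        with pytest.raises(ValueError):
            split_train_probe(net, 0.0, seed=0)
        with pytest.raises(ValueError):
            split_train_probe(nx.Graph([("a", "b")]), 0.8, seed=0)

    @pytest.mark.parametrize("net", seeded_er_graphs(10, n=16, seed0=900, p_lo=0.15))
    def test_partition_invariants(self, net):
        m = net.number_of_edges()
        split = split_train_probe(net, 0.8, seed=2)
        train = {canonical_pair(*e) for e in split.training.edges}
        source = {canonical_pair(*e) for e in net.edges}
        assert train | split.probe_edges == source
        assert not train & split.probe_edges
        assert set(split.training) == set(net)
        assert len(train) == min(math.floor(0.8 * m + 0.5), m - 1)
        assert len(split.probe_edges) >= 1


class TestAUCTallies:
    def test_hand_worked_comparison(self):
        # one probe score 2 against negatives {1, 2, 3}: one win, one tie, one loss
        est = auc_from_scores([2.0], [1.0, 2.0, 3.0])
        assert (est.n, est.n1, est.n2) == (3, 1, 1)
        assert est.auc == 0.5

    def test_perfect_and_constant(self):
        assert auc_from_scores([5.0, 6.0], [1.0, 2.0, 3.0]).auc == 1.0
        est = auc_from_scores([1.0] * 3, [1.0] * 4)
        assert est.auc == 0.5
        assert est.n2 == est.n == 12

    def test_empty_sides_rejected(self):
        with pytest.raises(EvaluationError):
            auc_from_scores([], [1.0])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20),
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20),
    )
    def test_identity_range_and_sign_reversal(self, probe, negative):
        est = auc_from_scores(probe, negative)
        assert 0.0 <= est.auc <= 1.0
        assert est.auc == (est.n1 + 0.5 * est.n2) / est.n
        assert est.n1 + est.n2 <= est.n
        flipped = auc_from_scores([-v for v in probe], [-v for v in negative])
        assert flipped.auc == pytest.approx(1.0 - est.auc, abs=1e-15)


class TestEstimateAUC:
    def test_perfect_planted_scorer(self):
        split = planted_split()
        probe = split.probe_edges

        def oracle(x, y):
            return 1.0 if canonical_pair(x, y) in probe else 0.0

        assert estimate_auc(split, oracle).auc == 1.0

    def test_constant_scorer(self):
        split = planted_split()
        est = estimate_auc(split, lambda x, y: 3.14)
        assert est.auc == 0.5
        assert est.n2 == est.n

    def test_rank_invariance_under_monotone_transform(self):
        split = planted_split()
        base = estimate_auc(split, "cn")
        transformed = estimate_auc(
            split, lambda x, y: 3.0 * get_cn(split, x, y) + 7.0
        )
        assert transformed.auc == pytest.approx(base.auc, abs=1e-12)

    def test_sign_reversal_maps_auc_to_complement(self):
        split = planted_split()
        base = estimate_auc(split, "cn")
        negated = estimate_auc(split, lambda x, y: -get_cn(split, x, y))
        assert negated.auc == pytest.approx(1.0 - base.auc, abs=1e-12)

    def test_negative_pool_modes(self):
        split = planted_split()
        source = estimate_auc(split, "cn", negative_pool="source")
        training = estimate_auc(split, "cn", negative_pool="training")
        # the training pool additionally contains the probe edges themselves
        assert training.n == source.n + len(split.probe_edges) ** 2
        with pytest.raises(ValueError):
            estimate_auc(split, "cn", negative_pool="bogus")

    def test_sampled_mode_identity_and_determinism(self):
        split = planted_split()
        a = estimate_auc(split, "cn", n_comparisons=2000, seed=17)
        b = estimate_auc(split, "cn", n_comparisons=2000, seed=17)
        assert a == b
        assert a.mode == "sampled"
        assert a.auc == (a.n1 + 0.5 * a.n2) / a.n

    def test_complete_graph_has_no_negative_pool(self):
        net = nx.complete_graph(6)
        split = split_train_probe(net, 0.8, seed=1)
        with pytest.raises(EvaluationError):
            estimate_auc(split, "cn", negative_pool="source")


def get_cn(split, x, y):
    return len(set(split.training.adj[x]) & set(split.training.adj[y]))


class TestRunExperiment:
    def test_single_run_degenerates(self):
        net = nx.gnp_random_graph(20, 0.25, seed=4)
        report = run_experiment(net, "cn", runs=1, base_seed=5)
        assert report.mean_auc == report.per_run_auc[0]
        assert report.sd_auc == 0.0

    def test_report_is_deterministic_and_recomputable(self):
        net = nx.gnp_random_graph(24, 0.2, seed=6)
        a = run_experiment(net, "ccpa", {"alpha": 0.5}, runs=4, base_seed=9)
        b = run_experiment(net, "ccpa", {"alpha": 0.5}, runs=4, base_seed=9)
        assert a.to_dict() == b.to_dict()
        mean = sum(a.per_run_auc) / len(a.per_run_auc)
        assert a.mean_auc == pytest.approx(mean, abs=1e-15)

    def test_adding_runs_preserves_earlier_ones(self):
        net = nx.gnp_random_graph(24, 0.2, seed=6)
        short = run_experiment(net, "cn", runs=3, base_seed=1)
        long = run_experiment(net, "cn", runs=6, base_seed=1)
        assert long.per_run_auc[:3] == short.per_run_auc

    def test_perfect_scorer_on_planted_benchmark(self):
        net, future = planted_benchmark(48, 0.2, seed=3)
        full = net.copy()
        full.add_edges_from(future)

        report = run_experiment(
            net, "cn", runs=2, base_seed=2
        )  # structural smoke: runs recorded
        assert len(report.per_run_auc) == 2

    def test_invalid_runs(self):
        with pytest.raises(ValueError):
            run_experiment(nx.cycle_graph(6), "cn", runs=0)


class TestAlphaSweep:
    def test_default_grid_shape(self):
        net = nx.gnp_random_graph(18, 0.25, seed=8)
        sweep = alpha_sweep(net, runs=2, base_seed=3)
        assert sweep.alphas == DEFAULT_ALPHA_GRID
        assert len(sweep.reports) == 9
        assert sweep.best_alpha in sweep.alphas
        best = max(r.mean_auc for r in sweep.reports)
        assert sweep.best_mean_auc == best

    def test_alpha_one_reproduces_cn_with_same_seeds(self):
        net = nx.gnp_random_graph(20, 0.25, seed=12)
        sweep = alpha_sweep(net, alphas=[1.0], runs=3, base_seed=21)
        cn = run_experiment(net, "cn", runs=3, base_seed=21)
        for a, b in zip(sweep.reports[0].per_run_auc, cn.per_run_auc):
            assert a == pytest.approx(b, abs=1e-12)

    def test_parameter_errors(self):
        net = nx.cycle_graph(8)
        with pytest.raises(ValueError):
            alpha_sweep(net, alphas=[])
        with pytest.raises(ValueError):
            alpha_sweep(net, alphas=[0.5, 1.1])

    def test_to_frame_columns(self):
        net = nx.gnp_random_graph(16, 0.3, seed=2)
        frame = alpha_sweep(net, alphas=[0.2, 0.8], runs=2, base_seed=1).to_frame()
        assert list(frame.columns) == ["alpha", "mean_auc", "sd_auc"]
        assert len(frame) == 2
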