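"""Generator calibration properties, exact-inference oracles and benchmarks."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import all_dags, dag_to_network
from ncpc.synthetic import (
    NoisyANDParams,
    SyntheticNetwork,
    benchmark_metrics,
    d_separation,
    exact_ci,
    exact_marginal,
    generate_network,
    noisy_and_target,
    rewire_hidden,
    rewire_time,
    run_benchmark,
    sample_dataset,
    simulate_study,
)


class TestGenerateNetwork:
    def test_single_node(self):
        net = generate_network(m=1, seed=0)
        assert net.node_names == ("X1",)
        assert net.parents["X1"] == ()

    def test_max_parent_count_bounded(self):
        for seed in range(30):
            net = generate_network(m=15, seed=seed)
            assert max(len(p) for p in net.parents.values()) <= 2

    def test_mean_parent_count_near_one_and_a_half(self):
        # measured over nodes with enough predecessors; the first nodes of
        # any topological order are structurally capped below their draw
        rng = np.random.default_rng(123)
        counts = []
        for _ in range(300):
            net = generate_network(m=15, rng=rng)
            topo = net.topological_order
            counts.extend(len(net.parents[n]) for n in topo[2:])
        assert np.mean(counts) == pytest.approx(1.5, abs=0.05)

    def test_mean_above_max_rejected(self):
        with pytest.raises(ValueError):
            generate_network(m=5, parent_count_max=2, parent_count_mean=3.0)

    def test_network_is_acyclic_by_construction(self):
        net = generate_network(m=15, seed=5)
        g = net.to_digraph()
        assert nx.is_directed_acyclic_graph(g)


class TestSampleDataset:
    def test_zero_probability_gives_zero_column(self):
        net = SyntheticNetwork(("A",), {"A": ()}, {"A": np.array(0.0)})
        df = sample_dataset(net, 50, seed=1)
        assert (df["A"] == 0).all()

    def test_deterministic_copy_cpt(self):
        net = SyntheticNetwork(
            ("A", "B"), {"A": (), "B": ("A",)},
            {"A": np.array(0.5), "B": np.array([0.0, 1.0])},
        )
        df = sample_dataset(net, 200, seed=2)
        assert (df["A"] == df["B"]).all()

    def test_empirical_marginals_match_exact_inference(self):
        rng = np.random.default_rng(3)
        net = dag_to_network(next(g for g in all_dags(4) if g.number_of_edges() >= 3),
                             rng=rng)
        n = 4000
        df = sample_dataset(net, n, seed=4)
        for node in net.node_names:
            p = exact_marginal(net, node)
            se = max(np.sqrt(p * (1 - p) / n), 1e-3)
            assert abs(df[node].mean() - p) < 3.5 * se


class TestNoisyAND:
    def test_noiseless_params_reduce_to_and(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 500).astype(np.int8)
        b = rng.integers(0, 2, 500).astype(np.int8)
        params = NoisyANDParams(1.0, 0.0, 0.0, 0.0)
        t = noisy_and_target(a, b, params, seed=6)
        np.testing.assert_array_equal(t, a & b)

    def test_closed_form_activity_for_independent_inputs(self):
        # E[P(T=1)] = 0.3^2 * 0.8 + (1 - 0.09) * 0.01 = 0.0811
        rng = np.random.default_rng(7)
        n = 200_000
        a = rng.integers(0, 2, n).astype(np.int8)
        b = rng.integers(0, 2, n).astype(np.int8)
        t = noisy_and_target(a, b, seed=8)
        assert t.mean() == pytest.approx(0.0811, abs=0.003)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            noisy_and_target([0, 1], [0, 1, 1], seed=0)


class TestRewireTime:
    @staticmethod
    def _topo_triple(net):
        order = net.topological_order
        return tuple(order[i] for i in (0, 1, 2))

    def test_requested_chain_correlations_achieved(self):
        net = generate_network(m=8, seed=9)
        triple = self._topo_triple(net)
        rw = rewire_time(net, triple, (0.75, 0.75, None))
        df = sample_dataset(rw, 10_000, seed=10)
        c12 = np.corrcoef(df[triple[0]], df[triple[1]])[0, 1]
        c13 = np.corrcoef(df[triple[0]], df[triple[2]])[0, 1]
        assert c12 == pytest.approx(0.75, abs=0.03)
        assert c13 < c12  # chain attenuates the end-to-end correlation

    def test_zero_correlation_decouples_chain(self):
        net = generate_network(m=8, seed=11)
        triple = self._topo_triple(net)
        rw = rewire_time(net, triple, (0.0, 0.0, None))
        df = sample_dataset(rw, 10_000, seed=12)
        assert abs(np.corrcoef(df[triple[0]], df[triple[1]])[0, 1]) < 0.03

    def test_marginal_preserved_along_chain(self):
        net = generate_network(m=8, seed=13)
        triple = self._topo_triple(net)
        rw = rewire_time(net, triple, (0.5, 0.5, None))
        p1 = exact_marginal(rw, triple[0])
        assert exact_marginal(rw, triple[1]) == pytest.approx(p1, abs=1e-9)
        assert exact_marginal(rw, triple[2]) == pytest.approx(p1, abs=1e-9)

    def test_invalid_r13_rejected(self):
        net = generate_network(m=6, seed=14)
        triple = self._topo_triple(net)
        with pytest.raises(ValueError):
            rewire_time(net, triple, (0.5, 0.5, 0.9))

    def test_cyclic_triple_rejected(self):
        net = SyntheticNetwork(
            ("A", "B", "C"), {"A": (), "B": ("A",), "C": ("B",)},
            {"A": np.array(0.5), "B": np.array([0.3, 0.7]),
             "C": np.array([0.3, 0.7])},
        )
        # forcing C -> A via the chain order (C, A, B) cycles through B -> C
        with pytest.raises(ValueError):
            rewire_time(net, ("C", "A", "B"), (0.5, 0.5, None))


class TestRewireHidden:
    def test_equal_pairwise_correlations(self):
        net = generate_network(m=8, seed=15)
        triple = tuple(net.topological_order[:3])
        marg = (0.45, 0.5, 0.55)
        rw = rewire_hidden(net, triple, 0.5, marginals=marg)
        df = sample_dataset(rw, 20_000, seed=16)
        cors = [
            np.corrcoef(df[a], df[b])[0, 1]
            for a, b in itertools.combinations(triple, 2)
        ]
        assert np.allclose(cors, 0.5, atol=0.03)

    def test_zero_correlation_gives_independence(self):
        net = generate_network(m=6, seed=17)
        triple = tuple(net.topological_order[:3])
        rw = rewire_hidden(net, triple, 0.0, marginals=(0.4, 0.5, 0.6))
        df = sample_dataset(rw, 10_000, seed=18)
        for a, b in itertools.combinations(triple, 2):
            assert abs(np.corrcoef(df[a], df[b])[0, 1]) < 0.03

    def test_hidden_column_absent_from_output(self):
        net = generate_network(m=6, seed=19)
        triple = tuple(net.topological_order[:3])
        rw = rewire_hidden(net, triple, 0.3, marginals=(0.5, 0.5, 0.5))
        df = sample_dataset(rw, 100, seed=20)
        assert set(df.columns) == set(net.node_names)
        assert rw.hidden_nodes and not rw.hidden_nodes & set(df.columns)

    def test_unachievable_correlation_rejected(self):
        net = generate_network(m=6, seed=21)
        triple = tuple(net.topological_order[:3])
        with pytest.raises(ValueError, match="unachievable"):
            rewire_hidden(net, triple, 0.75, marginals=(0.1, 0.5, 0.5))


class TestDSeparation:
    def test_textbook_chain(self):
        net = SyntheticNetwork(
            ("A", "B", "C"), {"A": (), "B": ("A",), "C": ("B",)},
            {"A": np.array(0.5), "B": np.array([0.2, 0.8]),
             "C": np.array([0.2, 0.8])},
        )
        assert d_separation(net, "A", "C", {"B"})
        assert not d_separation(net, "A", "C", set())

    def test_textbook_collider(self):
        net = SyntheticNetwork(
            ("A", "B", "C"), {"A": (), "B": (), "C": ("A", "B")},
            {"A": np.array(0.5), "B": np.array(0.5), "C": np.full((2, 2), 0.5)},
        )
        assert d_separation(net, "A", "B", set())
        assert not d_separation(net, "A", "B", {"C"})

    def test_unknown_node_rejected(self):
        net = SyntheticNetwork(("A",), {"A": ()}, {"A": np.array(0.5)})
        with pytest.raises(ValueError):
            d_separation(net, "A", "Z", set())

    def test_agrees_with_exact_ci_on_all_four_node_dags(self):
        """d-separation == exact CI in the joint distribution, for random
        non-degenerate CPTs (faithfulness holds almost surely)."""
        rng = np.random.default_rng(22)
        for g in all_dags(4):
            net = dag_to_network(g, rng=rng)
            names = net.node_names
            for x, y in itertools.combinations(names, 2):
                others = [n for n in names if n not in (x, y)]
                for k in range(len(others) + 1):
                    for z in itertools.combinations(others, k):
                        assert d_separation(net, x, y, z) == exact_ci(
                            net, x, y, z
                        ), (list(g.edges()), x, y, z)

    def test_agrees_with_networkx(self):
        rng = np.random.default_rng(23)
        for seed in range(20):
            net = generate_network(m=8, seed=seed)
            g = net.to_digraph()
            names = list(net.node_names)
            for _ in range(20):
                x, y, *z = rng.choice(names, size=4, replace=False)
                assert d_separation(net, x, y, z) == nx.is_d_separator(
                    g, {x}, {y}, set(z)
                )


class TestBenchmark:
    def test_metrics_examples(self):
        s = benchmark_metrics({"X1", "X2"}, {"X1", "X2"})
        assert s.correct and s.precision == 1.0 and s.recall == 1.0
        s = benchmark_metrics({"X1"}, {"X1", "X2"})
        assert not s.correct and s.precision == 1.0 and s.recall == 0.5
        s = benchmark_metrics({"X1", "X3"}, {"X1", "X2"})
        assert not s.correct and s.precision == 0.5 and s.recall == 0.5

    def test_empty_prediction_has_undefined_precision(self):
        s = benchmark_metrics(set(), {"X1"})
        assert np.isnan(s.precision) and s.recall == 0.0 and not s.correct

    def test_ground_truth_is_always_the_two_inputs(self):
        for seed in (1, 2):
            for scenario in ("time", "hidden"):
                data, net, truth = simulate_study(scenario, 0.5, 50, seed=seed)
                assert truth == set(net.ground_truth_neighbours)
                assert len(truth) == 2
                assert truth <= set(data.variable_names)

    def test_unknown_algorithm_rejected_before_simulation(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            run_benchmark("time", 0.5, 100, 1, algorithms=["nope"])

    def test_same_seed_reproduces_table(self):
        kwargs = dict(
            scenario="time", correlation=0.5, n_obs=120, reps=3,
            algorithms=["ncpc-dir-jnt", "pc-local"], seed=77,
        )
        a = run_benchmark(**kwargs)
        b = run_benchmark(**kwargs)
        assert a.equals(b)
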