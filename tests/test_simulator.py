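import numpy as np
import pytest

import grnbench as gb
from grnbench.simulator import (
    _CompiledModel,
    _regulation_map,
    hill_activation,
    hill_repression,
)


def chain_model(sign="activate", n=4.0, K=0.3, basal=(0.9, 0.8), leak=0.1):
    """Two-gene chain A -> B with explicit kinetics."""
    net = gb.GeneNetwork(nodes=["A", "B"], tf_flags={"A": True, "B": False},
                         edges={("A", "B"): gb.Edge("A", "B", sign=sign)})
    return gb.KineticModel(network=net,
                           basal={"A": basal[0], "B": basal[1]},
                           hill_n={("A", "B"): n}, hill_K={("A", "B"): K},
                           leak=leak, noise_sigma=0.0)


class TestGenerateSourceNetwork:
    def test_tf_count_is_ceiling_of_fraction(self):
        net = gb.generate_source_network(10, tf_fraction=0.3, seed=0)
        assert len(net.tfs) == 3

    @pytest.mark.parametrize("topology", ["scale_free", "erdos_renyi"])
    def test_same_seed_reproduces_edge_set(self, topology):
        a = gb.generate_source_network(40, topology=topology, seed=5)
        b = gb.generate_source_network(40, topology=topology, seed=5)
        assert a.edge_set() == b.edge_set()
        assert {k: e.sign for k, e in a.edges.items()} == \
            {k: e.sign for k, e in b.edges.items()}

    def test_network_is_weakly_connected_with_tf_only_regulators(self):
        import networkx as nx
        net = gb.generate_source_network(60, mean_degree=1.2, seed=3)
        assert nx.is_weakly_connected(net.to_digraph())
        assert all(net.tf_flags[r] for (r, _t) in net.edges)
        assert all(r != t for (r, t) in net.edges)

    def test_scale_free_has_heavier_hubs_than_erdos_renyi(self):
        def max_out(topology, seed):
            net = gb.generate_source_network(300, topology=topology,
                                             mean_degree=2.0, seed=seed)
            return max(n for _tf, n in gb.hub_degrees(net))

        sf = np.median([max_out("scale_free", s) for s in range(20)])
        er = np.median([max_out("erdos_renyi", s) for s in range(20)])
        assert sf > er

    def test_infeasible_density_raises(self):
        with pytest.raises(gb.ParameterizationError):
            gb.generate_source_network(10, tf_fraction=0.11, mean_degree=9.5,
                                       seed=0)

    def test_acyclic_by_default(self):
        import networkx as nx
        net = gb.generate_source_network(80, mean_degree=2.5, seed=9)
        assert nx.is_directed_acyclic_graph(net.to_digraph())


class TestSampleSubnetwork:
    def test_full_size_returns_whole_source(self, small_network):
        sub = gb.sample_subnetwork(small_network, len(small_network.nodes),
                                   seed=1)
        assert sub.edge_set() == small_network.edge_set()

    def test_determinism(self, small_network):
        a = gb.sample_subnetwork(small_network, 12, seed=7)
        b = gb.sample_subnetwork(small_network, 12, seed=7)
        assert a.nodes == b.nodes and a.edge_set() == b.edge_set()

    def test_denser_source_yields_denser_subnetworks(self):
        dense = gb.generate_source_network(150, mean_degree=3.5, seed=21)
        sparse = gb.generate_source_network(150, mean_degree=1.5, seed=21)
        n_dense = np.mean([gb.sample_subnetwork(dense, 50, seed=s).n_edges
                           for s in range(20)])
        n_sparse = np.mean([gb.sample_subnetwork(sparse, 50, seed=s).n_edges
                            for s in range(20)])
        assert n_dense > n_sparse

    def test_size_bounds(self, small_network):
        with pytest.raises(ValueError):
            gb.sample_subnetwork(small_network, 1, seed=0)
        with pytest.raises(ValueError):
            gb.sample_subnetwork(small_network,
                                 len(small_network.nodes) + 1, seed=0)


class TestAssignKinetics:
    def test_point_ranges_give_point_values(self, small_network):
        ranges = gb.KineticRanges(basal=(0.5, 0.5), hill_n=(2, 2),
                                  hill_K=(0.4, 0.4))
        model = gb.assign_kinetics(small_network, ranges, seed=0)
        assert all(v == 0.5 for v in model.basal.values())
        assert all(v == 2 for v in model.hill_n.values())
        assert all(v == 0.4 for v in model.hill_K.values())

    def test_determinism(self, small_network):
        a = gb.assign_kinetics(small_network, seed=3)
        b = gb.assign_kinetics(small_network, seed=3)
        assert a.basal == b.basal and a.hill_K == b.hill_K

    def test_sampled_parameters_respect_ranges(self):
        net = gb.generate_source_network(500, tf_fraction=0.3,
                                         mean_degree=4.0, seed=2)
        ranges = gb.KineticRanges(hill_K=(0.25, 0.65))
        model = gb.assign_kinetics(net, ranges, seed=4)
        ks = np.array(list(model.hill_K.values()))
        assert ks.size >= 2000
        assert ks.min() >= 0.25 and ks.max() <= 0.65

    def test_empty_network_rejected(self):
        empty = gb.GeneNetwork(nodes=[], tf_flags={})
        with pytest.raises(ValueError):
            gb.assign_kinetics(empty, seed=0)


class TestSteadyState:
    def test_half_saturation_identity(self):
        x = np.array([0.3])
        n = np.array([4.0])
        K = np.array([0.3])
        assert hill_activation(x, n, K)[0] == pytest.approx(0.5, abs=0)
        assert hill_repression(x, n, K)[0] == pytest.approx(0.5, abs=0)

    def test_unregulated_gene_sits_at_basal(self, small_model):
        ss = gb.steady_state(small_model)
        for g in small_model.network.nodes:
            if not small_model.network.regulators_of(g):
                assert ss[g] == pytest.approx(small_model.basal[g], abs=1e-9)

    def test_two_gene_chain_matches_closed_form(self):
        model = chain_model(sign="activate", n=3.0, K=0.25,
                            basal=(0.7, 0.9), leak=0.2)
        ss = gb.steady_state(model)
        a = 0.7
        act = a ** 3 / (0.25 ** 3 + a ** 3)
        expected_b = min(1.0, 0.9 * (0.2 + 0.8 * act))
        assert ss["A"] == pytest.approx(a, abs=1e-8)
        assert ss["B"] == pytest.approx(expected_b, abs=1e-8)

    def test_converged_state_is_a_fixed_point(self, small_model):
        ss = gb.steady_state(small_model)
        cm = _CompiledModel(small_model)
        x = np.array([[ss[g]] for g in cm.genes])
        fx = _regulation_map(cm, x, np.ones_like(x))
        assert np.abs(fx - x).max() < 1e-6

    def test_clamped_gene_fixed_and_target_responds_monotonically(self):
        model = chain_model(sign="activate")
        levels = [gb.steady_state(model, clamped={"A": a})["B"]
                  for a in (0.1, 0.3, 0.5, 0.9)]
        assert levels == sorted(levels)
        assert gb.steady_state(model, clamped={"A": 0.42})["A"] == 0.42

    def test_basal_multiplier_scales_unregulated_gene(self):
        model = chain_model()
        ss = gb.steady_state(model, basal_multipliers={"A": 0.5})
        assert ss["A"] == pytest.approx(0.45, abs=1e-8)

    def test_nonconvergence_names_a_cycle(self):
        net = gb.GeneNetwork(
            nodes=["A", "B"], tf_flags={"A": True, "B": True},
            edges={("A", "B"): gb.Edge("A", "B", sign="repress"),
                   ("B", "A"): gb.Edge("B", "A", sign="repress")})
        model = gb.KineticModel(network=net, basal={"A": 1.0, "B": 1.0},
                                hill_n={("A", "B"): 10.0, ("B", "A"): 10.0},
                                hill_K={("A", "B"): 0.5, ("B", "A"): 0.5},
                                leak=0.0, noise_sigma=0.0)
        with pytest.raises(gb.NonConvergenceError, match="A|B"):
            gb.steady_state(model, max_iter=3)


class TestSimulateExperiment:
    def test_knockdown_has_gene_count_plus_one_samples(self):
        net = gb.generate_source_network(100, seed=31)
        model = gb.assign_kinetics(net, seed=32)
        ds = gb.simulate_experiment(model, "knockdown", seed=33)
        assert ds.n_samples == 101
        assert ds.design == "knockdown"

    def test_knockdown_clamp_level_before_noise(self, small_network):
        ranges = gb.KineticRanges(noise_sigma=0.0)
        model = gb.assign_kinetics(small_network, ranges, seed=1)
        ds = gb.simulate_experiment(model, "knockdown", seed=2)
        for j, g in enumerate(ds.gene_ids):
            assert ds.values[j, j + 1] == pytest.approx(0.01, abs=1e-12)
            assert ds.perturbation_log[j + 1]["gene"] == g

    def test_zero_tau_zero_noise_multifactorial_equals_wildtype(
            self, small_network):
        ranges = gb.KineticRanges(noise_sigma=0.0)
        model = gb.assign_kinetics(small_network, ranges, seed=1)
        mf = gb.simulate_experiment(model, "multifactorial", n_samples=5,
                                    tau=0.0, seed=2)
        wt = gb.simulate_experiment(model, "wildtype", seed=3)
        assert np.allclose(mf.values, wt.values[:, [0] * 5])

    @pytest.mark.parametrize("n", [10, 50, 100, 200])
    def test_multifactorial_sample_counts(self, small_model, n):
        ds = gb.simulate_experiment(small_model, "multifactorial",
                                    n_samples=n, seed=4)
        assert ds.n_samples == n

    def test_bitwise_reproducibility_and_range(self, small_model):
        a = gb.simulate_experiment(small_model, "multifactorial",
                                   n_samples=20, seed=5)
        b = gb.simulate_experiment(small_model, "multifactorial",
                                   n_samples=20, seed=5)
        assert np.array_equal(a.values, b.values)
        assert a.values.min() >= 0.0 and a.values.max() <= 1.0


@pytest.fixture(scope="module")
def sparse_model():
    net = gb.generate_source_network(50, tf_fraction=0.16,
                                     mean_degree=1.2, seed=501)
    return gb.assign_kinetics(net, seed=502)


class TestMakeConditionPair:
    def test_zero_switches_gives_identical_models(self, sparse_model):
        ma, mb, manifest = gb.make_condition_pair(sparse_model, n_switches=0)
        assert manifest == []
        assert ma.network.edge_set() == mb.network.edge_set()

    def test_single_switch_moves_exactly_group_size_edges(self, sparse_model):
        ma, mb, manifest = gb.make_condition_pair(
            sparse_model, n_switches=1, switch_size=5, seed=7)
        only_a = ma.network.edge_set() - mb.network.edge_set()
        only_b = mb.network.edge_set() - ma.network.edge_set()
        assert len(only_a) == 5 and len(only_b) == 5
        (switch,) = manifest
        assert {t for (_r, t) in only_a} == set(switch.targets)
        assert all(r == switch.old_tf for (r, _t) in only_a)
        assert all(r == switch.new_tf for (r, _t) in only_b)

    def test_infeasible_switch_request_raises(self, sparse_model):
        with pytest.raises(gb.ParameterizationError):
            gb.make_condition_pair(sparse_model, n_switches=50,
                                   switch_size=10, seed=0)

    def test_switch_kinetics_carried_over(self, sparse_model):
        ma, mb, manifest = gb.make_condition_pair(
            sparse_model, n_switches=1, switch_size=3, seed=9)
        s = manifest[0]
        for t in s.targets:
            assert mb.hill_n[(s.new_tf, t)] == ma.hill_n[(s.old_tf, t)]
            assert mb.hill_K[(s.new_tf, t)] == ma.hill_K[(s.old_tf, t)]
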