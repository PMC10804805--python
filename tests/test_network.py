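"""Network assembly, execution-stack ordering (brute-force oracle),
buffer planning, the LSM prefab and config round-trips."""

import itertools

import numpy as np
import pytest

import snnkit as sk
from snnkit.network import allocate_buffers, compute_stack, order_groups


def brute_force_min_lts(ids, edges, eps):
    """Independent exhaustive oracle: minimum LTS over all permutations."""
    n = len(ids)
    index = {g: i for i, g in enumerate(ids)}
    edge_delay = {(index[s], index[t]): d for s, t, d in edges}
    best = np.inf
    for perm in itertools.permutations(range(n)):
        lts = 0.0
        for r in range(n):
            for c in range(r):
                lts += edge_delay.get((perm[r], perm[c]), -eps)
        best = min(best, lts)
    return best


class TestAdd:
    def test_synaptic_component_counts_are_products(self):
        net = sk.NetworkGraph()
        net.add("input", "in", 50)
        net.add("lif", "res", 125)
        net.add("ls", "syn", source="in", target="res", tau=8.0)
        assert net.groups["syn"].n == 6250

    def test_recurrent_group_size(self):
        net = sk.NetworkGraph()
        net.add("lif", "res", 125)
        net.add("ls", "rec", source="res", target="res")
        assert net.groups["rec"].n == 15625

    def test_duplicate_id_rejected(self):
        net = sk.NetworkGraph().add("lif", "a", 3)
        with pytest.raises(sk.ConfigError, match="duplicate"):
            net.add("lif", "a", 5)

    def test_dangling_source_rejected(self):
        net = sk.NetworkGraph().add("lif", "a", 3)
        with pytest.raises(sk.WiringError, match="unknown group"):
            net.add("ls", "syn", source="a", target="nope")

    def test_unknown_model_rejected(self):
        with pytest.raises(sk.ConfigError, match="unknown model"):
            sk.NetworkGraph().add("hodgkin", "a", 3)


class TestSetParam:
    def test_amend_tau_takes_effect_at_init(self):
        net = sk.NetworkGraph().add("lif", "a", 2, tau=10.0)
        net.set_param("a", "tau", 64.0)
        sim = sk.init(net, sk.SimClock(1.0, 5))
        assert sim.models["a"].decay == pytest.approx(np.exp(-1 / 64))

    def test_unknown_parameter_lists_valid_names(self):
        net = sk.NetworkGraph().add("lif", "a", 2)
        with pytest.raises(sk.ConfigError, match="tau"):
            net.set_param("a", "resistance", 5.0)

    def test_unknown_group_rejected(self):
        with pytest.raises(sk.ConfigError):
            sk.NetworkGraph().set_param("ghost", "tau", 1.0)


class TestStack:
    def test_feedforward_chain_is_topological(self):
        net = sk.NetworkGraph()
        net.add("input", "in", 2)
        net.add("lif", "out", 2)
        net.add("ls", "s", source="in", target="out")
        stack = compute_stack(net, 1.0)
        order = stack.order
        assert order.index("in") < order.index("s") < order.index("out")
        # no connection entries below the diagonal
        assert stack.lts == pytest.approx(-3 * stack.eps)

    def test_two_group_loop_cuts_at_cheapest_backward_edge(self):
        # I <-> O loop through synapses x (x->O delay 1) and y (y->I
        # delay 3): every ordering leaves at least one connection below
        # the diagonal; the minimum-LTS cut is the zero-delay edge I->x,
        # costing only the epsilon bookkeeping term.
        ids = ["I", "x", "O", "y"]
        edges = [("I", "x", 0.0), ("x", "O", 1.0),
                 ("O", "y", 0.0), ("y", "I", 3.0)]
        stack = order_groups(ids, edges, dt=1.0)
        assert stack.lts == pytest.approx(
            brute_force_min_lts(ids, edges, stack.eps), abs=1e-15
        )
        assert stack.order == ["x", "O", "y", "I"]
        assert stack.lts == pytest.approx(-5 * stack.eps)

    def test_loop_delay_variant_flips_order(self):
        ids = ["I", "x", "O", "y"]
        edges = [("I", "x", 0.0), ("x", "O", 2.0),
                 ("O", "y", 0.0), ("y", "I", 0.0)]
        stack = order_groups(ids, edges, dt=1.0)
        assert stack.order == ["I", "x", "O", "y"]

    def test_brute_force_oracle_agreement_on_random_networks(self):
        """On 200 random networks of <= 6 groups the chosen ordering's LTS
        equals the exhaustive-scan minimum."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(2, 7))
            ids = [f"g{i}" for i in range(n)]
            edges = []
            for s in range(n):
                for t in range(n):
                    if s != t and rng.random() < 0.35:
                        delay = float(rng.choice([0.0, 1.0, 2.0, 5.0]))
                        edges.append((ids[s], ids[t], delay))
            stack = order_groups(ids, edges, dt=1.0)
            oracle = brute_force_min_lts(ids, edges, stack.eps)
            assert stack.lts == pytest.approx(oracle, abs=1e-12)

    def test_random_dags_order_with_no_lower_connections(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            ids = [f"g{i}" for i in range(n)]
            edges = [
                (ids[s], ids[t], float(rng.integers(0, 4)))
                for s in range(n) for t in range(s + 1, n)
                if rng.random() < 0.5
            ]
            stack = order_groups(ids, edges, dt=1.0)
            # LTS contains only -eps entries: no connection went lower
            n_lower = n * (n - 1) // 2
            assert stack.lts == pytest.approx(-n_lower * stack.eps)

    def test_exhaustive_cap_requires_heuristic_flag(self):
        ids = [f"g{i}" for i in range(9)]
        edges = [(ids[i], ids[i + 1], 0.0) for i in range(8)]
        with pytest.raises(sk.ConfigError, match="heuristic"):
            order_groups(ids, edges)
        stack = order_groups(ids, edges, heuristic=True)
        assert stack.order == ids  # chain stays topological

    def test_heuristic_handles_cycles(self):
        ids = [f"g{i}" for i in range(10)]
        edges = [(ids[i], ids[(i + 1) % 10], float(i)) for i in range(10)]
        stack = order_groups(ids, edges, heuristic=True)
        assert sorted(stack.order) == sorted(ids)


class TestBuffers:
    def _loop_net(self):
        net = sk.NetworkGraph()
        net.add("input", "in", 2)
        net.add("lif", "res", 3)
        net.add("ls", "fwd", source="in", target="res")
        net.add("ls", "rec", source="res", target="res")
        net.set_ports("in", "res")
        return net

    def test_slot_count_equals_group_count(self):
        net = self._loop_net()
        plan = allocate_buffers(net, compute_stack(net, 1.0))
        assert len(plan.slots) == len(net.groups)

    def test_feedback_edge_reads_previous_step(self):
        net = self._loop_net()
        stack = compute_stack(net, 1.0)
        plan = allocate_buffers(net, stack)
        pos = {g: i for i, g in enumerate(stack.order)}
        for src, same in plan.read_map["rec"]:
            assert same == (pos[src] < pos["rec"])
        # the recurrent loop must contain exactly one feedback read
        feedback = [
            (g, src) for g in stack.order
            for src, same in plan.read_map[g] if not same
        ]
        assert len(feedback) == 1

    def test_reader_slots_alias_writer_slots(self):
        net = self._loop_net()
        plan = allocate_buffers(net, compute_stack(net, 1.0))
        for g, reads in plan.read_map.items():
            for src, _ in reads:
                assert plan.write_map[src] == src


class TestInit:
    def test_init_twice_is_deterministic(self):
        net = sk.build_lsm(n_in=5, n_res=8, n_out=2, nnz_in=6, nnz_res=10,
                           seed=3)
        a = sk.init(net, sk.SimClock(1.0, 10), seed=3)
        b = sk.init(net, sk.SimClock(1.0, 10), seed=3)
        assert a.stack.order == b.stack.order
        np.testing.assert_array_equal(
            a.models["syn_in"]._weight_matrix(),
            b.models["syn_in"]._weight_matrix(),
        )

    def test_aggregated_resolution_errors(self):
        net = sk.NetworkGraph()
        net.add("lif", "a", 2, tau=lambda b, s, r: np.ones((b, 99)))
        net.add("lif", "b", 2, tau=lambda b, s, r: np.ones((b, 98)))
        with pytest.raises(sk.ConfigError) as err:
            sk.init(net, sk.SimClock(1.0, 5))
        assert "'a'" in str(err.value) and "'b'" in str(err.value)


class TestBuildLSM:
    def test_default_group_sizes_match_reference_architecture(self):
        net = sk.build_lsm()
        assert net.groups["syn_in"].n == 6250
        assert net.groups["syn_res"].n == 15625
        assert net.groups["syn_out"].n == 1250
        sim = sk.init(net, sk.SimClock(1.0, 2), seed=0)
        assert len(sim.stack.order) == 6

    def test_nonzero_weight_counts(self):
        net = sk.build_lsm(seed=1)
        sim = sk.init(net, sk.SimClock(1.0, 2), seed=1)
        w_in = sim.models["syn_in"]._weight_matrix()
        w_res = sim.models["syn_res"]._weight_matrix()
        assert np.count_nonzero(w_in) == 200
        assert np.count_nonzero(w_res) == 2300

    def test_inhibitory_fraction_and_sign_structure(self):
        net = sk.build_lsm(seed=2, exc_fraction=0.8)
        sim = sk.init(net, sk.SimClock(1.0, 2), seed=2)
        w = sim.models["syn_res"]._weight_matrix()
        row_sign = np.sign(w.sum(axis=1))
        # each source neuron is consistently excitatory or inhibitory
        for row in w:
            nz = row[row != 0]
            if len(nz):
                assert np.all(nz > 0) or np.all(nz < 0)
        assert 0.5 < np.mean(row_sign[row_sign != 0] > 0) < 1.0

    def test_seed_reproducibility(self):
        a = sk.build_lsm(n_in=6, n_res=9, n_out=2, nnz_in=8, nnz_res=12, seed=5)
        b = sk.build_lsm(n_in=6, n_res=9, n_out=2, nnz_in=8, nnz_res=12, seed=5)
        np.testing.assert_array_equal(a.groups["syn_res"].params["w"],
                                      b.groups["syn_res"].params["w"])

    def test_excess_nnz_rejected(self):
        with pytest.raises(sk.ConfigError):
            sk.build_lsm(n_in=2, n_res=3, nnz_in=100)


class TestConfigRoundTrip:
    def test_yaml_round_trip_preserves_network(self, tmp_path):
        net = sk.NetworkGraph()
        net.add("input", "in", 3)
        net.add("lif", "hid", 4, tau=12.0, theta=0.9, rho=2.0)
        net.add("li", "out", 2, tau=30.0)
        net.add("ls", "s1", source="in", target="hid", tau=8.0,
                w=np.arange(12.0).reshape(3, 4).tolist(), delay=2.0)
        net.add("ls2", "s2", source="hid", target="out", tau_pos=15.0,
                tau_neg=5.0, w=0.1)
        net.set_ports("in", "out")
        path = tmp_path / "net.yaml"
        net.to_yaml(path)
        loaded = sk.NetworkGraph.from_yaml(path)
        assert loaded.to_config() == net.to_config()
        x = np.zeros((1, 5, 3))
        x[0, 0, :] = 1.0
        out_a = sk.init(net, sk.SimClock(1.0, 5), seed=0).run(x)
        out_b = sk.init(loaded, sk.SimClock(1.0, 5), seed=0).run(x)
        np.testing.assert_array_equal(out_a, out_b)

    def test_generator_params_refuse_serialization(self):
        net = sk.NetworkGraph()
        net.add("lif", "a", 2, tau=lambda b, s, r: np.ones((b, 2)))
        with pytest.raises(sk.ConfigError, match="generator"):
            net.to_config()
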