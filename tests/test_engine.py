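"""Clock-driven engine semantics: determinism, state continuity, monitor
neutrality, batch independence, feedback latency, buffer aliasing."""

import numpy as np
import pytest

import snnkit as sk


def chain_net(theta=0.8):
    net = sk.NetworkGraph()
    net.add("input", "in", 3)
    net.add("lif", "hid", 4, tau=12.0, theta=theta)
    net.add("li", "out", 2, tau=20.0)
    net.add("ls", "s1", source="in", target="hid", tau=8.0,
            w=np.random.default_rng(0).uniform(0.1, 0.4, (3, 4)))
    net.add("ls", "s2", source="hid", target="out", tau=8.0,
            w=np.random.default_rng(1).uniform(0.1, 0.4, (4, 2)))
    net.set_ports("in", "out")
    return net


def spikes(shape, p=0.2, seed=0):
    return (np.random.default_rng(seed).random(shape) < p).astype(float)


class TestRun:
    def test_zero_input_zero_output(self):
        sim = sk.init(chain_net(), sk.SimClock(1.0, 20))
        out = sim.run(np.zeros((2, 20, 3)))
        assert np.all(out == 0.0)

    def test_determinism_is_bitwise(self):
        x = spikes((2, 25, 3))
        a = sk.init(chain_net(), sk.SimClock(1.0, 25), seed=4).run(x)
        b = sk.init(chain_net(), sk.SimClock(1.0, 25), seed=4).run(x)
        np.testing.assert_array_equal(a, b)

    def test_batch_independence(self):
        x = spikes((4, 25, 3), seed=5)
        sim = sk.init(chain_net(), sk.SimClock(1.0, 25))
        full = sim.run(x)
        for b in range(4):
            single = sk.init(chain_net(), sk.SimClock(1.0, 25)).run(x[b:b + 1])
            np.testing.assert_array_equal(full[b], single[0])

    def test_split_run_state_continuity(self):
        x = spikes((2, 30, 3), seed=6)
        sim = sk.init(chain_net(), sk.SimClock(1.0, 30))
        whole = sim.run(x)
        sim2 = sk.init(chain_net(), sk.SimClock(1.0, 30))
        first = sim2.run(x[:, :15, :], reset=False)
        second = sim2.run(x[:, 15:, :], reset=False)
        np.testing.assert_array_equal(whole,
                                      np.concatenate([first, second], axis=1))

    def test_step_count_mismatch_rejected(self):
        sim = sk.init(chain_net(), sk.SimClock(1.0, 20))
        with pytest.raises(sk.WiringError, match="steps"):
            sim.run(np.zeros((1, 7, 3)))

    def test_component_mismatch_rejected(self):
        sim = sk.init(chain_net(), sk.SimClock(1.0, 20))
        with pytest.raises(sk.WiringError, match="components|port"):
            sim.run(np.zeros((1, 20, 9)))

    def test_nan_input_aborts_with_diagnostics(self):
        sim = sk.init(chain_net(), sk.SimClock(1.0, 5))
        x = np.zeros((1, 5, 3))
        x[0, 2, 1] = np.nan
        with pytest.raises(sk.NumericError, match="step 2"):
            sim.run(x)


class TestMonitors:
    def test_observer_neutrality(self):
        x = spikes((2, 25, 3), seed=7)
        plain = sk.init(chain_net(), sk.SimClock(1.0, 25)).run(x)
        sim = sk.init(chain_net(), sk.SimClock(1.0, 25))
        sim.set_monitor("hid", ["u", "out"])
        sim.set_monitor("s1", ["I", "out"])
        monitored = sim.run(x)
        np.testing.assert_array_equal(plain, monitored)

    def test_trace_shapes_follow_convention(self):
        x = spikes((2, 25, 3), seed=8)
        sim = sk.init(chain_net(), sk.SimClock(1.0, 25))
        sim.set_monitor("hid", ["u"])
        sim.set_monitor("s1", ["I"])
        sim.run(x)
        assert sim.get_monitored_results("hid")["u"].shape == (2, 25, 4)
        assert sim.get_monitored_results("s1")["I"].shape == (2, 25, 3, 4)

    def test_unknown_variable_lists_monitorables(self):
        sim = sk.init(chain_net(), sk.SimClock(1.0, 5))
        with pytest.raises(sk.ConfigError, match="'u'"):
            sim.set_monitor("hid", ["voltage"])

    def test_unmonitored_group_raises_on_retrieval(self):
        sim = sk.init(chain_net(), sk.SimClock(1.0, 5))
        with pytest.raises(sk.ConfigError, match="not monitored"):
            sim.get_monitored_results("hid")


class TestFeedbackSemantics:
    def _loop_sim(self, w_fwd=0.5, w_rec=0.3, tau=8.0):
        net = sk.NetworkGraph()
        net.add("input", "in", 1)
        net.add("li", "res", 1, tau=1e15)  # pure integrator for transparency
        net.add("ls", "fwd", source="in", target="res", tau=tau, w=w_fwd,
                integrate_output=False)
        net.add("ls", "rec", source="res", target="res", tau=tau, w=w_rec,
                integrate_output=False)
        net.set_ports("in", "res")
        return net

    def test_feedback_matches_hand_stepped_oracle(self):
        """The recurrent read observes exactly the previous step's output."""
        tau, w_fwd, w_rec = 8.0, 0.5, 0.3
        net = self._loop_sim(w_fwd, w_rec, tau)
        T = 12
        x = np.zeros((1, T, 1))
        x[0, 0, 0] = 1.0
        out = sk.init(net, sk.SimClock(1.0, T)).run(x)[0, :, 0]

        # independent hand-stepped oracle with an explicit one-step mailbox
        a1 = np.exp(-1.0 / tau)
        I_fwd = I_rec = u = 0.0
        prev_res_out = 0.0
        oracle = []
        for t in range(T):
            o_fwd = I_fwd
            I_fwd = I_fwd * a1 + w_fwd * (1.0 if t == 0 else 0.0)
            o_rec = I_rec
            I_rec = I_rec * a1 + w_rec * prev_res_out
            u = u + o_fwd + o_rec  # infinite-tau integrator
            prev_res_out = u
            oracle.append(u)
        np.testing.assert_allclose(out, oracle, rtol=1e-12)

    def test_buffer_aliasing_matches_naive_mailbox_simulator(self):
        """Slot-aliased execution equals a naive simulator that copies every
        group output into explicit per-edge mailboxes."""
        rng = np.random.default_rng(12)
        w1 = rng.uniform(0.2, 0.6, (2, 3))
        w2 = rng.uniform(-0.1, 0.3, (3, 3))
        net = sk.NetworkGraph()
        net.add("input", "in", 2)
        net.add("lif", "res", 3, tau=10.0, theta=0.6)
        net.add("ls", "fwd", source="in", target="res", tau=8.0, w=w1)
        net.add("ls", "rec", source="res", target="res", tau=8.0, w=w2)
        net.set_ports("in", "res")
        T = 20
        x = spikes((1, T, 2), p=0.4, seed=13)
        out = sk.init(net, sk.SimClock(1.0, T)).run(x)[0]

        # naive reference: every model stepped by hand, explicit mailboxes
        a1 = np.exp(-1.0 / 8.0)
        a2 = 8.0 * (1 - a1)
        decay = np.exp(-1.0 / 10.0)
        I1 = np.zeros((2, 3))
        I2 = np.zeros((3, 3))
        u = np.zeros(3)
        mailbox_res = np.zeros(3)  # previous-step reservoir spikes
        naive = []
        for t in range(T):
            o1 = (I1 * a2).sum(axis=0)
            I1 = I1 * a1 + w1 * x[0, t][:, None]
            o2 = (I2 * a2).sum(axis=0)
            I2 = I2 * a1 + w2 * mailbox_res[:, None]
            u = u * decay + o1 + o2
            s = (u >= 0.6).astype(float)
            u = np.where(s > 0, 0.0, u)
            mailbox_res = s
            naive.append(s)
        np.testing.assert_allclose(out, np.array(naive), atol=1e-12)


class TestMultiSegment:
    def test_single_segment_equals_run(self):
        x = spikes((2, 20, 3), seed=9)
        a = sk.init(chain_net(), sk.SimClock(1.0, 20)).run(x)
        b = sk.init(chain_net(), sk.SimClock(1.0, 20)).run_multi([(1.0, 20)], x)
        np.testing.assert_array_equal(a, b)

    def test_equal_dt_segments_merge(self):
        x = spikes((1, 30, 3), seed=10)
        a = sk.init(chain_net(), sk.SimClock(1.0, 30)).run(x)
        b = sk.init(chain_net(), sk.SimClock(1.0, 30)).run_multi(
            [(1.0, 10), (1.0, 20)], x)
        np.testing.assert_array_equal(a, b)

    def test_dt_change_refreshes_caches(self):
        x = spikes((1, 20, 3), seed=11)
        sim = sk.init(chain_net(), sk.SimClock(1.0, 20))
        sim.run_multi([(1.0, 10), (0.5, 10)], x)
        # after run_multi the nominal clock constants are restored
        assert sim.models["hid"].decay == pytest.approx(np.exp(-1 / 12.0))
        # and a dt change mid-run is visible in the output
        a = sim.run_multi([(1.0, 10), (1.0, 10)], x)
        b = sim.run_multi([(1.0, 10), (4.0, 10)], x)
        assert not np.array_equal(a, b)

    def test_zero_length_segment_rejected(self):
        sim = sk.init(chain_net(), sk.SimClock(1.0, 20))
        with pytest.raises(sk.ConfigError, match="segment"):
            sim.run_multi([(1.0, 0)], np.zeros((1, 0, 3)))


class TestDemoFixture:
    def test_batch_sweep_and_decay_ordering(self):
        net, clock, x = sk.demo_three_input_fixture()
        assert x.shape[0] == 10
        sim = sk.init(net, clock, batch_size=10)
        sim.set_monitor("out", ["u"])
        sim.run(x)
        traces = sim.get_monitored_results("out")["u"][:, :, 0]
        # traces differ across the time-constant sweep
        assert len({tuple(np.round(tr, 9)) for tr in traces}) == 10

    def test_membrane_decay_rate_follows_tau_sweep(self):
        # drive only the first 10 steps; afterwards the membrane decays
        # freely, so the tau=10 batch must shed potential faster than
        # the tau=100 batch (ratio comparison is immune to reset history)
        net, clock, x = sk.demo_three_input_fixture()
        x = x.copy()
        x[:, 10:, :] = 0.0
        sim = sk.init(net, clock, batch_size=10)
        sim.set_monitor("out", ["u"])
        sim.run(x)
        traces = sim.get_monitored_results("out")["u"][:, :, 0]
        ratio = traces[:, -1] / traces[:, -25]
        assert np.all(np.diff(ratio) > 0)  # slower decay for larger tau
        assert 0 < ratio[0] < ratio[-1] < 1
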