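import numpy as np
import pytest
from hypothesis import settings

import snnkit as sk
from snnkit import train as tr

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def toy_readout_net():
    """Feedforward net whose trained path has no spiking nonlinearity:
    4-channel spike input -> leaky synapse -> 5 leaky-integrator readouts."""
    rng = np.random.default_rng(0)
    net = sk.NetworkGraph()
    net.add("input", "in", 4)
    net.add("li", "out", 5, tau=20.0)
    net.add("ls", "syn", source="in", target="out", tau=8.0,
            w=rng.normal(0.0, 0.3, (4, 5)))
    net.set_ports("in", "out")
    T, B = 30, 6
    X = (rng.random((B, T, 4)) < 0.15).astype(float)
    y = rng.integers(0, 5, B)
    return net, X, y


@pytest.fixture
def small_lsm():
    """Desk-scale liquid state machine plus a separable 3-class rate task."""
    seed = 11
    X, y = sk.gen_rate_classes(n_classes=3, n_channels=20, T=100,
                               n_per_class=20, seed=seed)
    net = sk.build_lsm(n_in=20, n_res=60, n_out=3, nnz_in=100, nnz_res=500,
                       seed=seed)
    sim = sk.init(net, sk.SimClock(1.0, 100), batch_size=16, seed=seed)
    return net, sim, X, y


def make_trainable(sim, group_ids, **kwargs):
    cfg = tr.TrainerConfig(trainable_group_ids=list(group_ids), **kwargs)
    return tr.pair(sim, cfg)
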