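"""Reference desk-scale benchmark task.

A three-class rate-coded classification problem solved by a small liquid
state machine: 20 input channels, a 60-neuron recurrent LIF reservoir
(100 input and 500 recurrent non-zero synapses) and a 3-neuron
leaky-integrator readout, simulated for 100 one-millisecond steps.  Only
the reservoir-to-output weights are trained (30 epochs, ADAM, batch 16,
learning rate 5e-3, surrogate slope 10).  The sizes keep a full training
run in the tens of seconds on one CPU while exercising every stage the
full-scale tasks use: rate encoding, recurrent reservoir dynamics,
surrogate-gradient BPTT, and the post-training non-ideality sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SimClock
from .engine import init
from .network import NetworkGraph, build_lsm
from .synth import gen_rate_classes, train_test_split
from .train import TrainableModel, TrainerConfig, TrainHistory, fit, pair

__all__ = ["LsmBenchmarkResult", "run_lsm_rate_benchmark"]

#: reference parameters of the desk-scale task
N_CLASSES = 3
N_CHANNELS = 20
N_RESERVOIR = 60
NNZ_IN = 100
NNZ_RES = 500
T_STEPS = 100
N_PER_CLASS = 40
TEST_FRAC = 0.25
EPOCHS = 30
LEARNING_RATE = 5e-3
BATCH_SIZE = 16


@dataclass
class LsmBenchmarkResult:
    net: NetworkGraph
    model: TrainableModel
    history: TrainHistory
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray

    @property
    def test_accuracy(self) -> float:
        return self.history.test_acc[-1]


def run_lsm_rate_benchmark(seed: int, epochs: int = EPOCHS) -> LsmBenchmarkResult:
    """Generate the task, build and train the reference LSM under ``seed``."""
    X, y = gen_rate_classes(n_classes=N_CLASSES, n_channels=N_CHANNELS,
                            T=T_STEPS, n_per_class=N_PER_CLASS, seed=seed)
    Xtr, ytr, Xte, yte = train_test_split(X, y, TEST_FRAC, seed=seed)
    net = build_lsm(n_in=N_CHANNELS, n_res=N_RESERVOIR, n_out=N_CLASSES,
                    nnz_in=NNZ_IN, nnz_res=NNZ_RES, seed=seed)
    sim = init(net, SimClock(1.0, T_STEPS), batch_size=BATCH_SIZE, seed=seed)
    cfg = TrainerConfig(trainable_group_ids=["syn_out"], epochs=epochs,
                        learning_rate=LEARNING_RATE, batch_size=BATCH_SIZE,
                        seed=seed)
    model = pair(sim, cfg)
    history = fit(model, Xtr, ytr, Xte, yte)
    return LsmBenchmarkResult(net=net, model=model, history=history,
                              X_train=Xtr, y_train=ytr,
                              X_test=Xte, y_test=yte)
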