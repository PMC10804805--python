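"""Off-line supervised training of synaptic weights by surrogate-gradient
backpropagation-through-time (BPTT).

The forward pass is the plain clock-driven simulation — spike decisions
stay exact Heaviside steps, so training-time inference is bitwise identical
to the engine.  The backward pass propagates adjoints in reverse through
the time-steps and the execution stack, substituting the spike
nonlinearity's derivative with the normalized fast-sigmoid surrogate

    g(u) = 1 / (1 + beta * |u - theta|)^2

(peak 1 at threshold, slope parameter ``beta``).  Membrane resets and
refractory gates are treated as non-differentiable (detached), the
standard convention in surrogate-gradient SNN training.  Backpropagation
runs over the full sequence (no truncation; task sequences are a few
hundred steps at most).

Credit assignment reads the *peak membrane potential* of a non-spiking
(leaky-integrator) output layer: the per-class logit is the maximum over
time of that neuron's membrane trace, fed into a softmax log-likelihood
loss and optimized with ADAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfigError, InputModel, substream
from .engine import SimReadyNetwork
from .neurons import LI, LIF, Izhikevich
from .synapses import LeakySynapse1, LeakySynapse2

__all__ = [
    "TrainerConfig",
    "TrainHistory",
    "surrogate_spike",
    "surrogate_grad",
    "readout_logits",
    "nll_loss",
    "pair",
    "TrainableModel",
    "fit",
    "evaluate",
]


def surrogate_spike(u, theta, beta=10.0):
    """Forward spike function: exact Heaviside, ``u >= theta`` spikes.

    The backward counterpart is :func:`surrogate_grad`; together they form
    the spike nonlinearity with a custom derivative."""
    return (np.asarray(u) >= theta).astype(float)


def surrogate_grad(u, theta, beta=10.0):
    """Normalized fast-sigmoid pseudo-derivative of the spike function:
    ``1 / (1 + beta * |u - theta|)^2``; equals 1 at threshold and 1/4 at
    ``theta +/- 1/beta``."""
    if beta <= 0:
        raise ConfigError("surrogate slope beta must be positive")
    return 1.0 / (1.0 + beta * np.abs(np.asarray(u) - theta)) ** 2


def readout_logits(u_traces: np.ndarray) -> np.ndarray:
    """Max-over-time readout: logits[b, j] = max_t u_traces[b, t, j]."""
    return np.max(np.asarray(u_traces), axis=1)


def nll_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the softmax over logits."""
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_classes = logits.shape[1]
    if np.any(labels < 0) or np.any(labels >= n_classes):
        raise ConfigError(f"labels must lie in [0, {n_classes})")
    shifted = logits - logits.max(axis=1, keepdims=True)
    logz = np.log(np.sum(np.exp(shifted), axis=1))
    return float(np.mean(logz - shifted[np.arange(len(labels)), labels]))


def _softmax_grad(logits, labels):
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    p = e / e.sum(axis=1, keepdims=True)
    p[np.arange(len(labels)), labels] -= 1.0
    return p / len(labels)


@dataclass
class TrainerConfig:
    """Training hyperparameters.

    The surrogate slope default (beta = 10) and ADAM settings (lr = 1e-3,
    betas 0.9/0.999, eps 1e-8) are the field's customary defaults; they are
    recorded in the returned history's metadata.
    """

    trainable_group_ids: list = field(default_factory=list)
    beta: float = 10.0
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.beta <= 0:
            raise ConfigError("beta must be positive")
        if self.batch_size < 1 or self.epochs < 0:
            raise ConfigError("invalid batch_size/epochs")


@dataclass
class TrainHistory:
    """Per-epoch training record plus the end-of-training confusion matrix
    (rows: true class, columns: predicted; rows sum to per-class counts)."""

    loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    test_acc: list = field(default_factory=list)
    confusion: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


_SUPPORTED = (InputModel, LIF, LI, Izhikevich, LeakySynapse1, LeakySynapse2)


class TrainableModel:
    """A simulation-ready network exposed as a differentiable computation
    over selected synaptic weight matrices; everything else is frozen."""

    def __init__(self, simnet: SimReadyNetwork, cfg: TrainerConfig):
        if not getattr(simnet, "models", None):
            raise ConfigError("pair() requires an initialized network")
        self.simnet = simnet
        self.cfg = cfg
        for gid, model in simnet.models.items():
            if not isinstance(model, _SUPPORTED):
                raise ConfigError(
                    f"group {gid!r} uses {type(model).__name__}, which the "
                    "trainer does not differentiate through (delay and "
                    "refractory wrappers are inference-only)"
                )
        out_model = simnet.models[simnet.net.output_port]
        if not isinstance(out_model, LI):
            raise ConfigError(
                "peak-membrane readout requires a non-spiking (li) output "
                f"group; {simnet.net.output_port!r} is "
                f"{type(out_model).__name__} — use model 'li'"
            )
        self.trainable = list(cfg.trainable_group_ids)
        self._weights: dict[str, np.ndarray] = {}
        for gid in self.trainable:
            if gid not in simnet.models:
                raise ConfigError(f"unknown trainable group {gid!r}")
            model = simnet.models[gid]
            if not model.is_synapse:
                raise ConfigError(
                    f"trainable group {gid!r} is not a synaptic group"
                )
            # the trainer owns the authoritative trainable weights: model
            # objects are rebuilt from the network spec on re-batching, so
            # trained values must survive outside them
            self._weights[gid] = model._weight_matrix().copy()
            model.w = self._weights[gid]
        self._routes = self._build_routes()

    def _build_routes(self):
        pos = {g: i for i, g in enumerate(self.simnet.stack.order)}
        routes = {}
        for gid in self.simnet.stack.order:
            reads = self.simnet.plan.read_map[gid]
            routes[gid] = [(src, pos[src] < pos[gid]) for src, _ in reads]
        return routes

    # -- forward with tape -------------------------------------------------
    def forward(self, x: np.ndarray, record: bool = False):
        """Run the network on ``x [B, T, N_in]``; returns the output-port
        membrane traces ``[B, T, N_out]`` (and a tape when recording)."""
        sim = self.simnet
        x = np.asarray(x, dtype=sim.dtype)
        B, T = x.shape[0], x.shape[1]
        if B != sim.batch_size:
            sim._rebatch(B)
            for gid, w in self._weights.items():  # re-install trained weights
                sim.models[gid].w = w
        else:
            sim.reset()
        order = sim.stack.order
        in_port, out_port = sim.net.input_port, sim.net.output_port
        outputs = {g: np.zeros((T, B, sim.models[g].n_out), dtype=sim.dtype)
                   for g in order}
        tape = {g: {} for g in order} if record else None
        if record:
            for g in order:
                m = sim.models[g]
                if isinstance(m, LIF):
                    tape[g]["u_pre"] = np.zeros((T, B, m.n))
                    tape[g]["gate"] = np.zeros((T, B, m.n))
                    tape[g]["spikes"] = np.zeros((T, B, m.n))
                elif isinstance(m, Izhikevich):
                    tape[g]["v_sub"] = np.zeros((T, m.k, B, m.n))
                    tape[g]["v_final"] = np.zeros((T, B, m.n))
                    tape[g]["spikes"] = np.zeros((T, B, m.n))

        for t in range(T):
            sim.slots[in_port] = x[:, t, :]
            for gid in order:
                model = sim.models[gid]
                routes = self._routes[gid]
                if routes:
                    s = sim.slots[routes[0][0]]
                    for src, _same in routes[1:]:
                        s = s + sim.slots[src]
                elif gid == in_port:
                    s = sim.slots[gid]
                else:
                    s = np.zeros((B, model.n_in), dtype=sim.dtype)
                if record and isinstance(model, LIF):
                    u_prev = model.u
                    gate = model.gate
                    out = model.advance_timestep(s)
                    tape[gid]["u_pre"][t] = u_prev * model.decay + gate * s
                    tape[gid]["gate"][t] = gate
                    tape[gid]["spikes"][t] = out
                elif record and isinstance(model, Izhikevich):
                    v, u, h = model.v.copy(), model.u.copy(), model.h
                    out = model.advance_timestep(s)
                    for j in range(model.k):  # replay substeps for the tape
                        tape[gid]["v_sub"][t, j] = v
                        v_new = v + h * (0.04 * v * v + 5.0 * v + 140.0 - u + s)
                        u = (1.0 - h * model.a) * u + h * model.a * model.b * v
                        v = v_new
                    tape[gid]["v_final"][t] = v
                    tape[gid]["spikes"][t] = out
                else:
                    out = model.advance_timestep(s)
                sim.slots[gid] = np.asarray(out)
                outputs[gid][t] = out
        traces = np.transpose(outputs[out_port], (1, 0, 2))
        if record:
            return traces, outputs, tape
        return traces

    def _group_input(self, outputs, gid, t):
        total = None
        for src, same in self._routes[gid]:
            ts = t if same else t - 1
            val = outputs[src][ts] if ts >= 0 else np.zeros_like(outputs[src][0])
            total = val if total is None else total + val
        return total

    # -- backward ----------------------------------------------------------
    def loss_and_grads(self, x, labels):
        """Return ``(loss, grads)`` with one gradient array per trainable
        group, computed by full-sequence BPTT with the surrogate spike
        derivative."""
        sim = self.simnet
        traces, outputs, tape = self.forward(x, record=True)
        logits = readout_logits(traces)
        labels = np.asarray(labels, dtype=int)
        loss = nll_loss(logits, labels)
        dlogits = _softmax_grad(logits, labels)

        order = sim.stack.order
        out_port = sim.net.output_port
        B, T = x.shape[0], x.shape[1]
        adj_out = {g: np.zeros_like(outputs[g]) for g in order}
        # seed: max-over-time routes each logit's gradient to its arg-max step
        t_star = np.argmax(np.transpose(outputs[out_port], (1, 0, 2)), axis=1)
        for b in range(B):
            for j in range(dlogits.shape[1]):
                adj_out[out_port][t_star[b, j], b, j] += dlogits[b, j]

        grads = {g: np.zeros_like(sim.models[g].w) for g in self.trainable}
        carry = {}
        for gid in order:
            m = sim.models[gid]
            if isinstance(m, LeakySynapse1):
                carry[gid] = np.zeros((B, m.n_source, m.n_target))
            elif isinstance(m, LeakySynapse2):
                carry[gid] = (np.zeros((B, m.n_source, m.n_target)),
                              np.zeros((B, m.n_source, m.n_target)))
            elif isinstance(m, (LIF, LI)):
                carry[gid] = np.zeros((B, m.n))
            elif isinstance(m, Izhikevich):
                carry[gid] = (np.zeros((B, m.n)), np.zeros((B, m.n)))

        beta = self.cfg.beta
        for t in range(T - 1, -1, -1):
            for gid in reversed(order):
                m = sim.models[gid]
                lam_out = adj_out[gid][t]
                if isinstance(m, InputModel):
                    continue
                if isinstance(m, LeakySynapse1):
                    lam_next = carry[gid]  # adjoint of I(t+dt)
                    delta = self._group_input(outputs, gid, t)
                    if gid in grads:
                        grads[gid] += np.einsum("bst,bs->st", lam_next, delta)
                    lam_in = np.einsum("bst,st->bs", lam_next,
                                       m._weight_matrix())
                    carry[gid] = m.alpha1 * lam_next + \
                        m.phi * m.alpha2 * lam_out[:, None, :]
                    self._route_back(adj_out, gid, t, lam_in)
                elif isinstance(m, LeakySynapse2):
                    lam_p, lam_n = carry[gid]
                    delta = self._group_input(outputs, gid, t)
                    w = m._weight_matrix()
                    if gid in grads:
                        grads[gid] += np.einsum("bst,bs->st",
                                                lam_p - lam_n, delta)
                    lam_in = np.einsum("bst,st->bs", lam_p - lam_n, w)
                    carry[gid] = (
                        m.a1_pos * lam_p + m.phi * m.a2_pos * lam_out[:, None, :],
                        m.a1_neg * lam_n + m.phi * m.a2_neg * lam_out[:, None, :],
                    )
                    self._route_back(adj_out, gid, t, lam_in)
                elif isinstance(m, LIF):
                    lam_u = carry[gid]
                    rec = tape[gid]
                    s_t = rec["spikes"][t]
                    # reset is detached: gradient flows through non-reset path
                    lam_upre = lam_u * (1.0 - s_t) + lam_out * surrogate_grad(
                        rec["u_pre"][t], m.theta, beta
                    )
                    lam_in = rec["gate"][t] * lam_upre
                    carry[gid] = m.decay * lam_upre
                    self._route_back(adj_out, gid, t, lam_in)
                elif isinstance(m, LI):
                    lam_u = carry[gid] + lam_out
                    carry[gid] = m.decay * lam_u
                    self._route_back(adj_out, gid, t, lam_u)
                elif isinstance(m, Izhikevich):
                    lam_v, lam_u = carry[gid]
                    rec = tape[gid]
                    s_t = rec["spikes"][t]
                    lam_v = lam_v * (1.0 - s_t) + lam_out * surrogate_grad(
                        rec["v_final"][t], m.theta, beta
                    )
                    h, a, b = m.h, m.a, m.b
                    lam_in = np.zeros_like(lam_v)
                    for j in range(m.k - 1, -1, -1):
                        v_j = rec["v_sub"][t, j]
                        lam_in += h * lam_v
                        lam_v_prev = lam_v * (1.0 + h * (0.08 * v_j + 5.0)) \
                            + lam_u * (h * a * b)
                        lam_u = -h * lam_v + (1.0 - h * a) * lam_u
                        lam_v = lam_v_prev
                    carry[gid] = (lam_v, lam_u)
                    self._route_back(adj_out, gid, t, lam_in)
        return loss, grads

    def _route_back(self, adj_out, gid, t, lam_in):
        for src, same in self._routes[gid]:
            ts = t if same else t - 1
            if ts >= 0:
                adj_out[src][ts] += lam_in

    # -- weights -----------------------------------------------------------
    def get_weights(self, gid: str) -> np.ndarray:
        return self.simnet.models[gid]._weight_matrix().copy()

    def set_weights(self, gid: str, w: np.ndarray) -> None:
        w = np.asarray(w, dtype=float)
        if gid in self._weights:
            self._weights[gid] = w
        self.simnet.models[gid].w = w

    # -- inference ---------------------------------------------------------
    def predict(self, X: np.ndarray, chunk: int = 64) -> np.ndarray:
        preds = []
        for i in range(0, len(X), chunk):
            logits = readout_logits(self.forward(X[i:i + chunk]))
            preds.append(np.argmax(logits, axis=1))
        return np.concatenate(preds)


def pair(simnet: SimReadyNetwork, cfg: TrainerConfig) -> TrainableModel:
    """Pair a trainer configuration with an initialized network, exposing
    its forward pass as a differentiable computation over the selected
    synaptic weight groups (all other parameters frozen)."""
    return TrainableModel(simnet, cfg)


class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = {}
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            out[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def evaluate(model: TrainableModel, X, y):
    """Deterministic evaluation: returns (accuracy, confusion matrix)."""
    y = np.asarray(y, dtype=int)
    preds = model.predict(np.asarray(X))
    n_classes = model.simnet.models[model.simnet.net.output_port].n
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for truth, pred in zip(y, preds):
        confusion[truth, pred] += 1
    return float(np.mean(preds == y)), confusion


def fit(model: TrainableModel, X_train, y_train, X_test=None, y_test=None,
        cfg: TrainerConfig | None = None) -> TrainHistory:
    """Mini-batch ADAM training with per-epoch shuffling.

    Records loss and train/test accuracy per epoch and the end-of-training
    confusion matrix (on the test set when given, else the training set).
    """
    cfg = cfg or model.cfg
    X_train = np.asarray(X_train)
    y_train = np.asarray(y_train, dtype=int)
    if len(X_train) == 0:
        raise ConfigError("empty training dataset")
    n_classes = model.simnet.models[model.simnet.net.output_port].n
    if y_train.max() >= n_classes:
        raise ConfigError(
            f"label {y_train.max()} out of range for {n_classes} output "
            "neurons"
        )
    rng = substream(cfg.seed, "fit_shuffle")
    opt = _Adam({g: model.get_weights(g).shape for g in model.trainable},
                cfg.learning_rate)
    history = TrainHistory(metadata={
        "beta": cfg.beta, "learning_rate": cfg.learning_rate,
        "batch_size": cfg.batch_size, "epochs": cfg.epochs,
        "optimizer": "adam", "seed": cfg.seed,
        "trainable_groups": list(model.trainable),
    })
    for _epoch in range(cfg.epochs):
        perm = rng.permutation(len(X_train))
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            loss, grads = model.loss_and_grads(X_train[idx], y_train[idx])
            params = {g: model.get_weights(g) for g in model.trainable}
            new_params = opt.step(params, grads)
            for g, w in new_params.items():
                model.set_weights(g, w)
            epoch_loss += loss
            n_batches += 1
        history.loss.append(epoch_loss / max(n_batches, 1))
        train_acc, train_conf = evaluate(model, X_train, y_train)
        history.train_acc.append(train_acc)
        if X_test is not None:
            test_acc, test_conf = evaluate(model, X_test, y_test)
            history.test_acc.append(test_acc)
            history.confusion = test_conf
        else:
            history.confusion = train_conf
    return history
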