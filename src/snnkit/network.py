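"""Network assembly: groups, execution-stack computation, buffer planning.

A network is an unsorted collection of *groups* — neuron groups (nodes) and
synapse groups (edges carrying their source/target ids).  Before simulation
the groups must be linearized into an execution *stack*.  For every
candidate ordering a delay-substituted directed adjacency matrix (DAM) is
formed: entry [r, c] holds the connection delay from the group at position
r to the group at position c, and non-connections hold a negative
infinitesimal ``-eps``.  Connections landing in the strictly lower triangle
break same-step causality (the reader would need an output not yet
produced), so the ordering minimizing the lower-triangular sum (LTS) is
selected; the earliest ordering (in the order groups were added) attaining
the minimum wins.  For a feedforward network this reduces to a topological
order with a connection-free lower triangle; for recurrent networks the
lower-triangular connections become well-defined one-step recurrences.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import (
    ConfigError,
    InputModel,
    Model,
    WiringError,
    resolve_param,
    substream,
)
from .neurons import LI, LIF, Izhikevich, refractory_wrap
from .synapses import LeakySynapse1, LeakySynapse2, delay_wrap

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_REGISTRY",
    "GroupSpec",
    "NetworkGraph",
    "Stack",
    "BufferPlan",
    "order_groups",
    "compute_stack",
    "allocate_buffers",
    "build_lsm",
]

#: model-id -> (class, is_synapse); usable from config files and the CLI
MODEL_REGISTRY = {
    "input": InputModel,
    "lif": LIF,
    "li": LI,
    "izhikevich": Izhikevich,
    "ls": LeakySynapse1,
    "ls2": LeakySynapse2,
}

_SYNAPSE_MODELS = {"ls", "ls2"}
_MAX_EXHAUSTIVE = 8


@dataclass
class GroupSpec:
    """One group as declared by the user (resolved into a model at init)."""

    id: str
    model: str
    n: int | None = None
    source: str | None = None
    target: str | None = None
    delay: float = 0.0
    rho: float = 0.0
    params: dict = field(default_factory=dict)

    @property
    def is_synapse(self) -> bool:
        return self.model in _SYNAPSE_MODELS


@dataclass
class Stack:
    """Chosen execution order with its delay-substituted DAM and LTS."""

    order: list[str]
    dam: np.ndarray
    lts: float
    eps: float


@dataclass
class BufferPlan:
    """Temporary-storage layout: one output slot per group, readers aliased
    onto their source's slot.  ``read_map[g]`` lists ``(source_id,
    same_step)``; a False flag marks a feedback read of the previous
    engine step's value."""

    slots: dict
    write_map: dict
    read_map: dict


class NetworkGraph:
    """Programmatic network builder.

    Groups are added with :meth:`add`; synaptic groups name their source
    and target groups and derive their component count as
    ``N_src * N_tgt``.  The first-added group is the default input port and
    the last-added the default output port (override with
    :meth:`set_ports`).
    """

    def __init__(self):
        self.groups: dict[str, GroupSpec] = {}
        self._input_port: str | None = None
        self._output_port: str | None = None

    # -- construction ------------------------------------------------------
    def add(self, model: str, id: str, n: int | None = None, *,
            source: str | None = None, target: str | None = None,
            delay: float = 0.0, rho: float = 0.0, **params) -> "NetworkGraph":
        if id in self.groups:
            raise ConfigError(f"duplicate group id {id!r}")
        if model not in MODEL_REGISTRY:
            raise ConfigError(
                f"unknown model {model!r}; known: {sorted(MODEL_REGISTRY)}"
            )
        if model in _SYNAPSE_MODELS:
            if source is None or target is None:
                raise WiringError(
                    f"synaptic group {id!r} must name source and target groups"
                )
            for ref in (source, target):
                if ref not in self.groups:
                    raise WiringError(
                        f"synaptic group {id!r} references unknown group {ref!r}"
                    )
            n = self.groups[source].n * self.groups[target].n
        else:
            if n is None:
                raise ConfigError(f"neuron group {id!r} requires a component count n")
            if source is not None or target is not None:
                raise WiringError(f"neuron group {id!r} cannot name source/target")
        if delay < 0:
            raise ConfigError(f"group {id!r}: delay must be >= 0")
        self.groups[id] = GroupSpec(
            id=id, model=model, n=int(n), source=source, target=target,
            delay=float(delay), rho=float(rho), params=dict(params),
        )
        return self

    def set_param(self, id: str, name: str, value) -> "NetworkGraph":
        if id not in self.groups:
            raise ConfigError(f"unknown group {id!r}")
        spec = self.groups[id]
        if name == "delay":
            spec.delay = float(value)
        elif name == "rho":
            spec.rho = float(value)
        else:
            valid = self._valid_params(spec)
            if name not in valid:
                raise ConfigError(
                    f"group {id!r}: unknown parameter {name!r}; "
                    f"valid names: {sorted(valid)}"
                )
            spec.params[name] = value
        return self

    def _valid_params(self, spec: GroupSpec) -> set[str]:
        import inspect

        cls = MODEL_REGISTRY[spec.model]
        sig = inspect.signature(cls.__init__)
        names = set(sig.parameters) - {"self", "n", "n_source", "n_target"}
        return names

    def set_ports(self, input_port: str | None = None,
                  output_port: str | None = None) -> "NetworkGraph":
        for p in (input_port, output_port):
            if p is not None and p not in self.groups:
                raise ConfigError(f"unknown port group {p!r}")
        if input_port is not None:
            self._input_port = input_port
        if output_port is not None:
            self._output_port = output_port
        return self

    @property
    def input_port(self) -> str:
        if self._input_port is not None:
            return self._input_port
        if not self.groups:
            raise ConfigError("empty network has no ports")
        return next(iter(self.groups))

    @property
    def output_port(self) -> str:
        if self._output_port is not None:
            return self._output_port
        if not self.groups:
            raise ConfigError("empty network has no ports")
        return list(self.groups)[-1]

    # -- graph view --------------------------------------------------------
    def edges(self) -> list[tuple[str, str, float]]:
        """Directed group-to-group connections as (src, dst, delay).

        Each synaptic group contributes a zero-delay edge from its source
        neuron group into itself, and an edge from itself into its target
        carrying the synapse's output delay.
        """
        out = []
        for spec in self.groups.values():
            if spec.is_synapse:
                out.append((spec.source, spec.id, 0.0))
                out.append((spec.id, spec.target, spec.delay))
        return out

    # -- model instantiation ----------------------------------------------
    def instantiate(self, id: str, batch_size: int, seed: int) -> Model:
        """Build the model object for one group, resolving its parameters
        (including generator functions) on a per-group random substream."""
        spec = self.groups[id]
        cls = MODEL_REGISTRY[spec.model]
        rng = substream(seed, "params", id)
        resolved = {}
        if spec.is_synapse:
            n_src = self.groups[spec.source].n
            n_tgt = self.groups[spec.target].n
            shape = (n_src, n_tgt)
            args = {"n_source": n_src, "n_target": n_tgt}
        else:
            shape = (spec.n,)
            args = {"n": spec.n}
        for name, value in spec.params.items():
            resolved[name] = resolve_param(
                value, batch_size, shape, rng, group=id, name=name
            )
        model = cls(**args, **resolved)
        if spec.rho > 0 and spec.model != "lif":
            model = refractory_wrap(model, spec.rho)
        elif spec.rho > 0:
            model.rho = spec.rho
        if spec.delay > 0:
            model = delay_wrap(model, spec.delay)
        return model

    # -- config round-trip -------------------------------------------------
    def to_config(self) -> dict:
        groups = []
        for spec in self.groups.values():
            entry = {"model": spec.model, "id": spec.id}
            if not spec.is_synapse:
                entry["n"] = spec.n
            else:
                entry["source"] = spec.source
                entry["target"] = spec.target
            if spec.delay:
                entry["delay"] = spec.delay
            if spec.rho:
                entry["rho"] = spec.rho
            for k, v in spec.params.items():
                if callable(v):
                    raise ConfigError(
                        f"group {spec.id!r}: generator-function parameter "
                        f"{k!r} cannot be serialized to a config file"
                    )
                entry[k] = v.tolist() if isinstance(v, np.ndarray) else v
            groups.append(entry)
        return {
            "groups": groups,
            "ports": {"input": self.input_port, "output": self.output_port},
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "NetworkGraph":
        net = cls()
        for entry in cfg["groups"]:
            entry = dict(entry)
            model = entry.pop("model")
            gid = entry.pop("id")
            n = entry.pop("n", None)
            source = entry.pop("source", None)
            target = entry.pop("target", None)
            delay = entry.pop("delay", 0.0)
            rho = entry.pop("rho", 0.0)
            params = {
                k: np.asarray(v, dtype=float) if isinstance(v, list) else v
                for k, v in entry.items()
            }
            net.add(model, gid, n, source=source, target=target,
                    delay=delay, rho=rho, **params)
        ports = cfg.get("ports") or {}
        net.set_ports(ports.get("input"), ports.get("output"))
        return net

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkGraph":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


# -- stack computation -----------------------------------------------------

def _lts(perm_idx, delay, has_edge, eps):
    """Lower-triangular sum of the delay-substituted DAM for one ordering."""
    sub_delay = delay[np.ix_(perm_idx, perm_idx)]
    sub_edge = has_edge[np.ix_(perm_idx, perm_idx)]
    lower = np.tri(len(perm_idx), k=-1, dtype=bool)
    return np.sum(np.where(sub_edge, sub_delay, -eps)[lower])


def order_groups(ids, edges, dt: float = 1.0, *, heuristic: bool = False,
                 eps: float | None = None):
    """Choose an execution order for ``ids`` minimizing the LTS.

    ``edges`` is a list of ``(src, dst, delay)``.  Exhaustive enumeration is
    used up to 8 groups; larger networks require ``heuristic=True``, which
    removes maximal-delay back-edges until the graph is acyclic and
    topologically sorts the rest.

    Returns a :class:`Stack`.
    """
    ids = list(ids)
    n = len(ids)
    if n == 0:
        raise ConfigError("cannot order an empty network")
    if eps is None:
        eps = 1e-9 * dt
    index = {g: i for i, g in enumerate(ids)}
    delay = np.zeros((n, n))
    has_edge = np.zeros((n, n), dtype=bool)
    for src, dst, d in edges:
        if src not in index or dst not in index:
            raise WiringError(f"edge ({src!r} -> {dst!r}) references unknown group")
        if d < 0:
            raise ConfigError("connection delays must be >= 0")
        has_edge[index[src], index[dst]] = True
        delay[index[src], index[dst]] = d

    if n <= _MAX_EXHAUSTIVE:
        best_perm, best_lts = None, np.inf
        for perm in itertools.permutations(range(n)):
            val = _lts(list(perm), delay, has_edge, eps)
            if val < best_lts:  # strictly better: earliest minimum wins
                best_lts, best_perm = val, perm
        order_idx = list(best_perm)
    elif heuristic:
        order_idx = _heuristic_order(n, delay, has_edge)
    else:
        raise ConfigError(
            f"{n} groups exceed the exhaustive ordering cap "
            f"({_MAX_EXHAUSTIVE}); pass heuristic=True to use greedy ordering"
        )

    dam = np.where(
        has_edge[np.ix_(order_idx, order_idx)],
        delay[np.ix_(order_idx, order_idx)],
        -eps,
    )
    lts = float(np.sum(dam[np.tri(n, k=-1, dtype=bool)]))
    order = [ids[i] for i in order_idx]
    for r in range(n):
        for c in range(r):
            if has_edge[order_idx[r], order_idx[c]] and \
                    delay[order_idx[r], order_idx[c]] == 0:
                logger.warning(
                    "zero-delay connection %r -> %r is lower-triangular and "
                    "carries one engine step of implicit latency",
                    order[r], order[c],
                )
    return Stack(order=order, dam=dam, lts=lts, eps=eps)


def _heuristic_order(n, delay, has_edge):
    """Greedy large-network ordering: drop max-delay back-edges until the
    remaining graph is acyclic, then topologically sort (stable in the
    order groups were added)."""
    edges = {(r, c): delay[r, c] for r in range(n) for c in range(n)
             if has_edge[r, c]}
    removed = set()
    while True:
        order = _topo_or_none(n, {e for e in edges if e not in removed})
        if order is not None:
            return order
        # remove the largest-delay edge participating in a cycle
        cyc_edges = sorted(
            (e for e in edges if e not in removed),
            key=lambda e: (-edges[e], e),
        )
        removed.add(cyc_edges[0])


def _topo_or_none(n, edge_set):
    indeg = [0] * n
    adj = [[] for _ in range(n)]
    for r, c in edge_set:
        adj[r].append(c)
        indeg[c] += 1
    ready = [i for i in range(n) if indeg[i] == 0]
    out = []
    while ready:
        i = ready.pop(0)
        out.append(i)
        for j in adj[i]:
            indeg[j] -= 1
            if indeg[j] == 0:
                ready.append(j)
        ready.sort()
    return out if len(out) == n else None


def compute_stack(net: NetworkGraph, dt: float, *,
                  heuristic: bool = False) -> Stack:
    """Compute the execution stack of a network for step size ``dt``."""
    if not net.groups:
        raise ConfigError("cannot compute a stack for an empty network")
    return order_groups(list(net.groups), net.edges(), dt, heuristic=heuristic)


def allocate_buffers(net: NetworkGraph, stack: Stack) -> BufferPlan:
    """Alias every reader's input address onto its source's output slot.

    Feedback readers (source later in the stack) observe the value written
    in the *previous* engine step — the defined recurrence semantics.
    """
    position = {g: i for i, g in enumerate(stack.order)}
    for port in (net.input_port, net.output_port):
        if port not in position:
            raise ConfigError(f"port group {port!r} missing from the stack")
    write_map = {g: g for g in stack.order}  # one slot per group, own id
    read_map = {g: [] for g in stack.order}
    for src, dst, _delay in net.edges():
        same_step = position[src] < position[dst]
        read_map[dst].append((src, same_step))
    slots = {g: None for g in stack.order}
    return BufferPlan(slots=slots, write_map=write_map, read_map=read_map)


# -- prefab: liquid state machine ------------------------------------------

def build_lsm(
    n_in: int = 50,
    n_res: int = 125,
    n_out: int = 10,
    tau_neuron: float = 64.0,
    tau_syn: float = 8.0,
    nnz_in: int = 200,
    nnz_res: int = 2300,
    exc_fraction: float = 0.8,
    theta: float = 1.0,
    w_in_scale: float = 0.05,
    w_res_scale: float = 0.02,
    w_out_scale: float = 0.01,
    phi_res: float = 1.0,
    seed: int = 0,
) -> NetworkGraph:
    """Build a liquid-state-machine network: input -> recurrent LIF
    reservoir -> non-spiking LI readout.

    The input-to-reservoir synapse group gets exactly ``nnz_in`` non-zero
    weights (positive, uniform support); the reservoir-to-reservoir group
    gets ``nnz_res`` non-zero weights whose sign follows an excitatory /
    inhibitory assignment of the source neuron (``exc_fraction`` of the
    reservoir excitatory).  Readout weights start from a small symmetric
    uniform distribution.  Fully reproducible under ``seed``.
    """
    for name, v in (("n_in", n_in), ("n_res", n_res), ("n_out", n_out)):
        if v < 1:
            raise ConfigError(f"{name} must be positive")
    if nnz_in > n_in * n_res:
        raise ConfigError("nnz_in exceeds input-to-reservoir group size")
    if nnz_res > n_res * n_res:
        raise ConfigError("nnz_res exceeds reservoir-to-reservoir group size")

    rng = substream(seed, "build_lsm")
    w_in = np.zeros(n_in * n_res)
    idx = rng.choice(n_in * n_res, size=nnz_in, replace=False)
    w_in[idx] = w_in_scale * rng.uniform(0.5, 1.5, size=nnz_in)
    w_in = w_in.reshape(n_in, n_res)

    excitatory = rng.random(n_res) < exc_fraction
    w_res = np.zeros(n_res * n_res)
    idx = rng.choice(n_res * n_res, size=nnz_res, replace=False)
    w_res[idx] = w_res_scale * rng.uniform(0.5, 1.5, size=nnz_res)
    w_res = w_res.reshape(n_res, n_res)
    w_res[~excitatory, :] *= -1.0  # inhibitory source neurons

    # readout starts excitatory so output membranes rise and peak late,
    # which keeps the max-over-time credit assignment deep in time
    w_out = w_out_scale * rng.uniform(0.0, 1.0, size=(n_res, n_out))

    net = NetworkGraph()
    net.add("input", "in", n_in)
    net.add("lif", "res", n_res, tau=tau_neuron, theta=theta)
    net.add("li", "out", n_out, tau=tau_neuron)
    net.add("ls", "syn_in", source="in", target="res", tau=tau_syn, w=w_in)
    net.add("ls", "syn_res", source="res", target="res", tau=tau_syn,
            w=w_res, phi=phi_res)
    net.add("ls", "syn_out", source="res", target="out", tau=tau_syn, w=w_out)
    net.set_ports("in", "out")
    logger.info(
        "LSM built: %d/%d/%d neurons, synapse groups %d/%d/%d",
        n_in, n_res, n_out, n_in * n_res, n_res * n_res, n_res * n_out,
    )
    return net
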