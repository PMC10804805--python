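"""Clock-driven simulation engine.

Two nested loops drive the simulation: the outer loop walks the time-steps
of the clock, the inner loop traverses the execution stack and, for each
group, (a) reads its input from the temporary-storage slots, (b) calls the
model's ``advance_timestep``, and (c) writes the group output back onto its
slot.  Slot contents are overwritten every step; monitors copy out selected
state/output variables as the simulation runs, without perturbing it.

The external input is written into the input port's slot before the inner
loop of each step; the output port's slot is collected after the inner
loop.  Feedback readers (sources later in the stack) observe the previous
step's slot value; slots start zeroed, so the first feedback read is zero.
"""

from __future__ import annotations

import numpy as np

from .core import (
    ConfigError,
    NumericError,
    SignalTensor,
    SimClock,
    WiringError,
)
from .network import NetworkGraph, allocate_buffers, compute_stack

__all__ = ["SimReadyNetwork", "init"]


class SimReadyNetwork:
    """A network consolidated for simulation: resolved parameters, stack,
    buffer plan, and instantiated models.  Reusable across ``run`` calls.
    """

    def __init__(self, net: NetworkGraph, clock: SimClock, *,
                 batch_size: int = 1, seed: int = 0, heuristic: bool = False,
                 single_precision: bool = False):
        self.net = net
        self.clock = clock
        self.seed = int(seed)
        self.batch_size = int(batch_size)
        self.dtype = np.float32 if single_precision else np.float64
        self.stack = compute_stack(net, clock.dt, heuristic=heuristic)
        self.plan = allocate_buffers(net, self.stack)
        self._monitors: dict[str, list[str]] = {}
        self._traces: dict[tuple[str, str], list] = {}
        self._build_models()

    # -- construction ------------------------------------------------------
    def _build_models(self) -> None:
        errors = []
        self.models = {}
        for gid in self.stack.order:
            try:
                model = self.net.instantiate(gid, self.batch_size, self.seed)
                model.dtype = self.dtype
                model.time_dep(self.clock.dt)
                model.set_initial_state(self.batch_size)
                self.models[gid] = model
            except Exception as exc:  # aggregate resolution failures
                errors.append(f"group {gid!r}: {exc}")
        if errors:
            raise ConfigError(
                "network initialization failed:\n  " + "\n  ".join(errors)
            )
        self._reset_slots()

    def _reset_slots(self) -> None:
        self.slots = {
            gid: np.zeros((self.batch_size, m.n_out), dtype=self.dtype)
            for gid, m in self.models.items()
        }

    def reset(self) -> None:
        """Re-zero every group state and slot (parameters untouched)."""
        for model in self.models.values():
            model.set_initial_state(self.batch_size)
        self._reset_slots()
        self._traces = {}

    def _rebatch(self, batch_size: int) -> None:
        self.batch_size = int(batch_size)
        self._build_models()

    # -- monitoring --------------------------------------------------------
    def set_monitor(self, group_id: str, variables) -> None:
        """Record the listed state/output variables of a group every step."""
        if group_id not in self.models:
            raise ConfigError(f"unknown group {group_id!r}")
        model = self.models[group_id]
        variables = [variables] if isinstance(variables, str) else list(variables)
        valid = model.monitorable()
        for var in variables:
            if var not in valid:
                raise ConfigError(
                    f"group {group_id!r} has no monitorable variable "
                    f"{var!r}; available: {sorted(valid)}"
                )
        self._monitors[group_id] = variables

    def get_monitored_results(self, group_id: str) -> dict[str, np.ndarray]:
        """Return monitored traces for one group as ``{var: [B, T, ...]}``."""
        if group_id not in self._monitors:
            raise ConfigError(f"group {group_id!r} is not monitored")
        out = {}
        for var in self._monitors[group_id]:
            frames = self._traces.get((group_id, var), [])
            out[var] = np.stack(frames, axis=1) if frames else np.empty(0)
        return out

    # -- simulation --------------------------------------------------------
    def run(self, external_input, *, reset: bool = True) -> np.ndarray:
        """Simulate the clock's steps driven by ``external_input``
        ``[B, T, N_in]``; returns the output-port signal ``[B, T, N_out]``.

        With ``reset=False`` the state carried from a previous call is
        reused, resuming the simulation (the input then only needs as many
        steps as it provides)."""
        x = external_input.data if isinstance(external_input, SignalTensor) \
            else np.asarray(external_input, dtype=self.dtype)
        if x.ndim != 3:
            raise WiringError(
                f"external input must be [batch, time, components], "
                f"got shape {x.shape}"
            )
        in_port, out_port = self.net.input_port, self.net.output_port
        if x.shape[2] != self.models[in_port].n_in:
            raise WiringError(
                f"input has {x.shape[2]} components; input port "
                f"{in_port!r} expects {self.models[in_port].n_in}"
            )
        if reset and x.shape[1] != self.clock.n_steps:
            raise WiringError(
                f"input has {x.shape[1]} steps; clock expects "
                f"{self.clock.n_steps}"
            )
        if x.shape[0] != self.batch_size:
            self._rebatch(x.shape[0])
            self._traces = {}
        elif reset:
            self.reset()

        n_steps = x.shape[1]
        collected = np.zeros(
            (self.batch_size, n_steps, self.models[out_port].n_out),
            dtype=self.dtype,
        )
        for t in range(n_steps):
            self.slots[in_port] = x[:, t, :].astype(self.dtype, copy=False)
            self._advance_one_step(t)
            collected[:, t, :] = self.slots[out_port]
        return collected

    def _advance_one_step(self, t: int) -> None:
        in_port = self.net.input_port
        for gid in self.stack.order:
            model = self.models[gid]
            reads = self.plan.read_map[gid]
            if reads:
                s = self.slots[reads[0][0]]
                for src, _same in reads[1:]:
                    s = s + self.slots[src]
            elif gid == in_port:
                s = self.slots[gid]  # externally written before the loop
            else:
                s = np.zeros((self.batch_size, model.n_in), dtype=self.dtype)
            try:
                out = model.advance_timestep(s)
            except NumericError as exc:
                raise NumericError(f"step {t}, group {gid!r}: {exc}") from exc
            if not np.all(np.isfinite(out)):
                raise NumericError(
                    f"step {t}: group {gid!r} produced non-finite output"
                )
            self.slots[gid] = np.asarray(out)
            if gid in self._monitors:
                for var in self._monitors[gid]:
                    value = out if var == "out" else getattr(model, var)
                    self._traces.setdefault((gid, var), []).append(
                        np.array(value, copy=True)
                    )

    def run_multi(self, segments, external_input) -> np.ndarray:
        """Run a sequence of ``(dt, n_steps)`` segments on one input tensor.

        Between segments every model's ``time_dep`` is re-invoked with the
        new dt; state carries across segment boundaries."""
        x = external_input.data if isinstance(external_input, SignalTensor) \
            else np.asarray(external_input, dtype=self.dtype)
        segments = [(float(dt), int(n)) for dt, n in segments]
        for dt, n in segments:
            if n < 1:
                raise ConfigError("zero-length segment")
            if dt <= 0:
                raise ConfigError("segment dt must be positive")
        total = sum(n for _, n in segments)
        if x.shape[1] != total:
            raise WiringError(
                f"input provides {x.shape[1]} steps; segments require {total}"
            )
        if x.shape[0] != self.batch_size:
            self._rebatch(x.shape[0])
        else:
            self.reset()
        outputs = []
        offset = 0
        for dt, n in segments:
            for model in self.models.values():
                model.time_dep(dt)
            outputs.append(self.run(x[:, offset:offset + n, :], reset=False))
            offset += n
        # restore the nominal clock constants
        for model in self.models.values():
            model.time_dep(self.clock.dt)
        return np.concatenate(outputs, axis=1)


def init(net: NetworkGraph, clock: SimClock, *, batch_size: int = 1,
         seed: int = 0, heuristic: bool = False,
         single_precision: bool = False) -> SimReadyNetwork:
    """Consolidate a network for simulation (stack, buffers, models)."""
    return SimReadyNetwork(
        net, clock, batch_size=batch_size, seed=seed, heuristic=heuristic,
        single_precision=single_precision,
    )
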