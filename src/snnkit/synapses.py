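"""Leaky synapse groups (1st and 2nd order), output delay, weight access.

A synaptic group connects every component of a source group to every
component of a target group (fully connected by construction); pruning is
expressed by zero weights.  Per presynaptic spike the 1st-order model adds
``w`` to an exponentially decaying current, and the group output towards
target j integrates the current over the time-step:

    I(t+dt) = I(t) * exp(-dt/tau) + w * spikes(t)
    O_j(t)  = phi * sum_i I_ij(t) * tau * (1 - exp(-dt/tau))

Note the printed-equation ordering: the output is computed from the
*pre-update* state, so a spike arriving at the synapse influences the
target one engine step later.  The 2nd-order model tracks separate
positive/negative branches whose difference forms a double-exponential
(alpha-like) kernel.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import ConfigError, Model, NumericError, WiringError

__all__ = [
    "LeakySynapse1",
    "LeakySynapse2",
    "DelayWrapper",
    "delay_wrap",
    "set_weights",
    "get_weights",
]


class _SynapseBase(Model):
    is_synapse = True
    spiking = False

    def __init__(self, n_source, n_target, w=0.0, phi=1.0, integrate_output=True):
        super().__init__(int(n_source) * int(n_target))
        self.n_source = int(n_source)
        self.n_target = int(n_target)
        self.n_in = self.n_source
        self.n_out = self.n_target
        self.w = w
        self.phi = phi
        self.integrate_output = bool(integrate_output)

    def _weight_matrix(self) -> np.ndarray:
        w = np.asarray(self.w, dtype=float)
        if w.ndim == 0:
            return np.broadcast_to(w, (self.n_source, self.n_target))
        try:
            return np.broadcast_to(w, (self.n_source, self.n_target))
        except ValueError as exc:
            raise WiringError(
                f"weight matrix shape {w.shape} does not broadcast to "
                f"[{self.n_source}, {self.n_target}]"
            ) from exc

    def _check_spikes(self, spikes):
        spikes = np.asarray(spikes)
        if spikes.shape[-1] != self.n_source:
            raise WiringError(
                f"synapse expects {self.n_source} source components, "
                f"got {spikes.shape[-1]}"
            )
        if not np.all(np.isfinite(spikes)):
            raise NumericError("non-finite spike input into synapse group")
        return spikes


class LeakySynapse1(_SynapseBase):
    """First-order leaky synapse group.

    Parameters
    ----------
    n_source, n_target : source/target component counts (N = product)
    tau : per-synapse decay constant (> 0), scalar or [N_src, N_tgt]
    w : weight matrix [N_src, N_tgt] (zeros = pruned)
    phi : group-wise scalar scaling factor
    integrate_output : include the tau*(1-exp(-dt/tau)) time-step
        integration factor in the output (on by default)
    """

    state_vars = ("I",)

    def __init__(self, n_source, n_target, tau=10.0, w=0.0, phi=1.0,
                 integrate_output=True):
        super().__init__(n_source, n_target, w=w, phi=phi,
                         integrate_output=integrate_output)
        self.tau = tau
        self.alpha1 = None
        self.alpha2 = None

    def time_dep(self, dt):
        super().time_dep(dt)
        tau = np.asarray(self.tau, dtype=float)
        if np.any(tau <= 0):
            raise ConfigError("tau must be positive")
        self.alpha1 = np.exp(-dt / tau)
        self.alpha2 = tau * (1.0 - self.alpha1) if self.integrate_output else 1.0

    def set_initial_state(self, batch_size):
        super().set_initial_state(batch_size)
        self.I = np.zeros((batch_size, self.n_source, self.n_target),
                          dtype=self.dtype)
        self.out = np.zeros((batch_size, self.n_target), dtype=self.dtype)

    def advance_timestep(self, spikes):
        self._require_state()
        spikes = self._check_spikes(spikes)
        # output from the pre-update state (printed-equation order)
        O = self.phi * np.sum(self.I * self.alpha2, axis=1)
        self.I = self.I * self.alpha1 + self._weight_matrix() * spikes[..., None]
        self.out = O
        return O


class LeakySynapse2(_SynapseBase):
    """Second-order leaky synapse group (double-exponential kernel).

    Two current branches are advanced independently — the positive one with
    decay ``tau_pos`` receiving ``+w`` per spike, the negative one with
    ``tau_neg`` receiving ``-w`` — and both contribute to the integrated
    output.  ``tau_pos != tau_neg`` is recommended (equal values collapse
    the kernel to zero).
    """

    state_vars = ("I_pos", "I_neg")

    def __init__(self, n_source, n_target, tau_pos=15.0, tau_neg=5.0, w=0.0,
                 phi=1.0, integrate_output=True):
        super().__init__(n_source, n_target, w=w, phi=phi,
                         integrate_output=integrate_output)
        self.tau_pos = tau_pos
        self.tau_neg = tau_neg

    def time_dep(self, dt):
        super().time_dep(dt)
        tp = np.asarray(self.tau_pos, dtype=float)
        tn = np.asarray(self.tau_neg, dtype=float)
        if np.any(tp <= 0) or np.any(tn <= 0):
            raise ConfigError("tau_pos and tau_neg must be positive")
        self.a1_pos = np.exp(-dt / tp)
        self.a1_neg = np.exp(-dt / tn)
        if self.integrate_output:
            self.a2_pos = tp * (1.0 - self.a1_pos)
            self.a2_neg = tn * (1.0 - self.a1_neg)
        else:
            self.a2_pos = self.a2_neg = 1.0

    def set_initial_state(self, batch_size):
        super().set_initial_state(batch_size)
        shape = (batch_size, self.n_source, self.n_target)
        self.I_pos = np.zeros(shape, dtype=self.dtype)
        self.I_neg = np.zeros(shape, dtype=self.dtype)
        self.out = np.zeros((batch_size, self.n_target), dtype=self.dtype)

    def advance_timestep(self, spikes):
        self._require_state()
        spikes = self._check_spikes(spikes)
        O = self.phi * np.sum(
            self.I_pos * self.a2_pos + self.I_neg * self.a2_neg, axis=1
        )
        w = self._weight_matrix()
        drive = w * spikes[..., None]
        self.I_pos = self.I_pos * self.a1_pos + drive
        self.I_neg = self.I_neg * self.a1_neg - drive
        self.out = O
        return O


class DelayWrapper(Model):
    """Shift a model's output by ``delay`` time units along the time axis.

    The delay discretizes to ``round(delay/dt)`` engine steps (ties to
    even); sub-dt delays round to zero with a warning.  Steps before the
    first delayed sample emit zeros, so the total emitted signal is
    conserved up to the tail still buffered at the end of a run.
    """

    def __init__(self, inner: Model, delay: float):
        if delay < 0:
            raise ConfigError(f"delay must be >= 0, got {delay}")
        super().__init__(inner.n)
        self.inner = inner
        self.is_synapse = inner.is_synapse
        self.spiking = inner.spiking
        self.n_in = inner.n_in
        self.n_out = inner.n_out
        self.delay = float(delay)
        self.n_delay_steps = 0

    def time_dep(self, dt):
        super().time_dep(dt)
        self.inner.time_dep(dt)
        self.n_delay_steps = int(round(self.delay / dt))
        if self.delay > 0 and self.n_delay_steps == 0:
            warnings.warn(
                f"delay {self.delay} is below dt={dt}; rounded to 0 steps",
                stacklevel=2,
            )

    def set_initial_state(self, batch_size):
        super().set_initial_state(batch_size)
        self.inner.set_initial_state(batch_size)
        self._buffer = [
            np.zeros((batch_size, self.n_out), dtype=self.dtype)
            for _ in range(self.n_delay_steps)
        ]

    def advance_timestep(self, x):
        self._require_state()
        raw = self.inner.advance_timestep(x)
        if self.n_delay_steps == 0:
            self.out = raw
            return raw
        self._buffer.append(np.asarray(raw))
        delayed = self._buffer.pop(0)
        self.out = delayed
        return delayed

    def monitorable(self):
        return self.inner.state_vars + ("out",)

    def __getattr__(self, name):
        inner = self.__dict__.get("inner")
        if inner is not None and (
            name in inner.state_vars or name in ("w", "phi", "n_source", "n_target")
        ):
            return getattr(inner, name)
        raise AttributeError(name)


def delay_wrap(model: Model, delay: float) -> Model:
    """Wrap ``model`` so its output is shifted by ``delay`` time units."""
    if delay == 0:
        return model
    return DelayWrapper(model, delay)


def set_weights(group: Model, w) -> None:
    """Install a weight matrix on a synaptic group (zeros = pruned)."""
    target = group.inner if isinstance(group, DelayWrapper) else group
    if not target.is_synapse:
        raise ConfigError("set_weights applies to synaptic groups only")
    w = np.asarray(w, dtype=float)
    if w.ndim > 0:
        try:
            np.broadcast_shapes(w.shape, (target.n_source, target.n_target))
        except ValueError as exc:
            raise WiringError(
                f"weight shape {w.shape} does not broadcast to "
                f"[{target.n_source}, {target.n_target}]"
            ) from exc
    target.w = w


def get_weights(group: Model) -> np.ndarray:
    """Return the group's dense [N_src, N_tgt] weight matrix."""
    target = group.inner if isinstance(group, DelayWrapper) else group
    if not target.is_synapse:
        raise ConfigError("get_weights applies to synaptic groups only")
    return target._weight_matrix().copy()
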