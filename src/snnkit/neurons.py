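"""Neuron models: leaky integrate-and-fire, leaky integrator, Izhikevich.

All models are time-discrete update rules over vectorized state ``[B, N]``.
The LIF and LI updates are the exact solutions of the leaky ODE sampled on
the clock grid; the Izhikevich model is integrated by forward-Euler
substeps.  Spike detection uses ``u >= theta`` (equality spikes) and the
reset applies to the state carried into the next step.
"""

from __future__ import annotations

import numpy as np

from .core import ConfigError, LifecycleError, Model, NumericError

__all__ = ["LIF", "LI", "Izhikevich", "RefractoryWrapper", "refractory_wrap"]


def _check_finite(x: np.ndarray, who: str) -> None:
    if not np.all(np.isfinite(x)):
        raise NumericError(f"non-finite input into {who}")


class LIF(Model):
    """Leaky integrate-and-fire neuron with optional refractoriness.

    Membrane update ``u' = u * exp(-dt/tau) + gate * S``; a spike is emitted
    where ``u' >= theta``, after which ``u`` resets to ``u_rest`` and input
    integration is gated off (``gate = 0``) for a time ``rho``.  The gate
    multiplies only the input term — the membrane keeps decaying during the
    refractory window.

    Parameters
    ----------
    n : component count
    tau : membrane time constant (> 0), scalar or per-component / per-batch
    theta : firing threshold
    u_rest : rest/reset potential
    rho : refractory duration in time units (0 disables refractoriness)
    """

    state_vars = ("u", "gate", "t_since_spike")
    spiking = True

    def __init__(self, n, tau=10.0, theta=1.0, u_rest=0.0, rho=0.0):
        super().__init__(n)
        self.tau = tau
        self.theta = theta
        self.u_rest = u_rest
        self.rho = rho
        self.decay = None

    def time_dep(self, dt):
        super().time_dep(dt)
        tau = np.asarray(self.tau, dtype=float)
        if np.any(tau <= 0):
            raise ConfigError("tau must be positive")
        if np.any(np.asarray(self.rho) < 0):
            raise ConfigError("rho must be >= 0")
        self.decay = np.exp(-dt / tau)

    def set_initial_state(self, batch_size):
        super().set_initial_state(batch_size)
        shape = (batch_size, self.n)
        self.u = np.broadcast_to(
            np.asarray(self.u_rest, dtype=self.dtype), shape
        ).copy()
        self.gate = np.ones(shape, dtype=self.dtype)
        # start outside any refractory window
        self.t_since_spike = np.full(shape, np.inf, dtype=self.dtype)
        self.out = np.zeros(shape, dtype=self.dtype)

    def advance_timestep(self, S):
        self._require_state()
        S = np.asarray(S)
        _check_finite(S, f"LIF(n={self.n})")
        u = self.u * self.decay + self.gate * S
        spikes = (u >= self.theta).astype(self.dtype)
        fired = spikes > 0
        u = np.where(fired, np.broadcast_to(np.asarray(self.u_rest), u.shape), u)
        self.t_since_spike = np.where(fired, 0.0, self.t_since_spike + self.dt)
        if np.any(np.asarray(self.rho) > 0):
            self.gate = np.where(self.t_since_spike >= self.rho, 1.0, 0.0)
        else:
            self.gate = np.ones_like(u)
        self.u = u
        self.out = spikes
        return spikes


class LI(Model):
    """Non-spiking leaky integrator: LIF dynamics without threshold/reset.

    Outputs the membrane potential itself; used as an analog readout layer.
    """

    state_vars = ("u",)
    spiking = False

    def __init__(self, n, tau=10.0):
        super().__init__(n)
        self.tau = tau
        self.decay = None

    def time_dep(self, dt):
        super().time_dep(dt)
        tau = np.asarray(self.tau, dtype=float)
        if np.any(tau <= 0):
            raise ConfigError("tau must be positive")
        self.decay = np.exp(-dt / tau)

    def set_initial_state(self, batch_size):
        super().set_initial_state(batch_size)
        self.u = np.zeros((batch_size, self.n), dtype=self.dtype)
        self.out = self.u

    def advance_timestep(self, S):
        self._require_state()
        S = np.asarray(S)
        _check_finite(S, f"LI(n={self.n})")
        self.u = self.u * self.decay + S
        self.out = self.u
        return self.u


class Izhikevich(Model):
    """Two-variable Izhikevich neuron integrated by forward-Euler substeps.

    Per engine step, ``k = ceil(1/h)`` substeps of

        v <- v + h * (0.04 v^2 + 5 v + 140 - u + S)
        u <- (1 - h a) u + h a b v

    are performed, then a spike is emitted where ``v >= theta`` and the
    state resets (``v <- c``, ``u <- u + d``).  The equations carry their
    own millisecond timescale: one engine step advances the model by one
    model-time unit regardless of ``dt`` (rescale inputs if ``dt != 1`` in
    the model's native units).  Refractoriness is intrinsic to the dynamics.

    Default constants (regular spiking): a=0.02, b=0.2, c=-65, d=8,
    theta=30.  ``h`` in (0, 1] drives numerical stability.
    """

    state_vars = ("v", "u")
    spiking = True

    def __init__(self, n, a=0.02, b=0.2, c=-65.0, d=8.0, theta=30.0, h=1.0):
        super().__init__(n)
        if not (0 < h <= 1):
            raise ConfigError(f"substep parameter h must be in (0, 1], got {h}")
        self.a, self.b, self.c, self.d = a, b, c, d
        self.theta = theta
        self.h = float(h)
        self.k = int(np.ceil(1.0 / h))

    def set_initial_state(self, batch_size):
        super().set_initial_state(batch_size)
        shape = (batch_size, self.n)
        self.v = np.broadcast_to(np.asarray(self.c, dtype=self.dtype), shape).copy()
        self.u = np.asarray(self.b, dtype=self.dtype) * self.v
        self.out = np.zeros(shape, dtype=self.dtype)

    def advance_timestep(self, S):
        self._require_state()
        S = np.asarray(S)
        _check_finite(S, f"Izhikevich(n={self.n})")
        v, u, h = self.v, self.u, self.h
        a, b = self.a, self.b
        for _ in range(self.k):
            v_new = v + h * (0.04 * v * v + 5.0 * v + 140.0 - u + S)
            u = (1.0 - h * a) * u + h * a * b * v
            v = v_new
        spikes = (v >= self.theta).astype(self.dtype)
        fired = spikes > 0
        self.v = np.where(fired, np.broadcast_to(np.asarray(self.c), v.shape), v)
        self.u = np.where(fired, u + self.d, u)
        self.out = spikes
        return spikes


class RefractoryWrapper(Model):
    """Gate input integration of any spiking model for a time ``rho`` after
    each of its spikes (the same mechanism LIF implements natively)."""

    state_vars = ("gate", "t_since_spike")
    spiking = True

    def __init__(self, inner: Model, rho: float):
        if not inner.spiking:
            raise ConfigError(
                "refractory_wrap requires a spiking model; "
                f"{type(inner).__name__} is non-spiking"
            )
        if rho < 0:
            raise ConfigError(f"rho must be >= 0, got {rho}")
        super().__init__(inner.n)
        self.inner = inner
        self.rho = float(rho)
        self.is_synapse = inner.is_synapse

    def time_dep(self, dt):
        super().time_dep(dt)
        self.inner.time_dep(dt)

    def set_initial_state(self, batch_size):
        super().set_initial_state(batch_size)
        self.inner.set_initial_state(batch_size)
        shape = (batch_size, self.n)
        self.gate = np.ones(shape, dtype=self.dtype)
        self.t_since_spike = np.full(shape, np.inf, dtype=self.dtype)

    def advance_timestep(self, S):
        self._require_state()
        spikes = self.inner.advance_timestep(self.gate * np.asarray(S))
        fired = spikes > 0
        self.t_since_spike = np.where(fired, 0.0, self.t_since_spike + self.dt)
        if self.rho > 0:
            self.gate = np.where(self.t_since_spike >= self.rho, 1.0, 0.0)
        self.out = spikes
        return spikes

    def monitorable(self):
        return self.state_vars + self.inner.state_vars + ("out",)

    def __getattr__(self, name):
        # expose inner state (u, v, ...) to monitors
        inner = self.__dict__.get("inner")
        if inner is not None and name in inner.state_vars:
            return getattr(inner, name)
        raise AttributeError(name)


def refractory_wrap(model: Model, rho: float) -> Model:
    """Return ``model`` with post-spike integration gating; no-op if rho=0."""
    if rho == 0:
        return model
    return RefractoryWrapper(model, rho)
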