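"""Core conventions of the simulator: tensors, clocks, parameters, model lifecycle.

Every signal exchanged between groups is a dense array following the axis
order ``[batch, time, components]`` (a single time-slice drops the time
axis: ``[batch, components]``).  Spike signals are {0,1}-valued; analog
signals are unconstrained reals.  All quantities are unitless numbers — the
user owns unit consistency.  Examples throughout the documentation use the
millisecond/millivolt convention (``dt`` in ms, rates in Hz).

A *model* governs a *group* of identically-behaved components and follows a
three-method lifecycle:

``time_dep(dt)``
    pre-computes every dt-dependent constant (e.g. ``exp(-dt/tau)``);
``set_initial_state(batch_size)``
    allocates and initializes all state arrays;
``advance_timestep(x)``
    consumes one input time-slice and returns one output time-slice,
    updating only its own state.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

SPIKE = "spike"
ANALOG = "analog"

__all__ = [
    "SPIKE",
    "ANALOG",
    "SignalTensor",
    "SimClock",
    "resolve_param",
    "substream",
    "Model",
    "SnnError",
    "ConfigError",
    "WiringError",
    "ParameterShapeError",
    "LifecycleError",
    "NumericError",
]


class SnnError(Exception):
    """Base class for simulator errors."""


class ConfigError(SnnError):
    """Invalid configuration (model choice, wrapper usage, ports...)."""


class WiringError(SnnError):
    """Inconsistent network wiring (shapes, dangling group ids...)."""


class ParameterShapeError(SnnError):
    """A resolved parameter does not broadcast to its group's shape."""


class LifecycleError(SnnError):
    """Model lifecycle methods called out of order."""


class NumericError(SnnError):
    """Non-finite values encountered during simulation."""


@dataclass
class SignalTensor:
    """Dense signal array in ``[batch, time, components]`` order.

    ``kind`` is ``"spike"`` (values restricted to {0, 1}) or ``"analog"``.
    """

    data: np.ndarray
    kind: str = ANALOG

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.kind not in (SPIKE, ANALOG):
            raise ConfigError(f"unknown signal kind {self.kind!r}")
        if self.data.ndim not in (2, 3):
            raise ConfigError(
                "signal must be [batch, time, components] or a "
                f"[batch, components] slice, got ndim={self.data.ndim}"
            )
        if self.kind == SPIKE:
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ConfigError("spike signals must be {0,1}-valued")

    @classmethod
    def spikes(cls, data: np.ndarray) -> "SignalTensor":
        return cls(data, SPIKE)

    @classmethod
    def analog(cls, data: np.ndarray) -> "SignalTensor":
        return cls(data, ANALOG)

    @property
    def batch_size(self) -> int:
        return self.data.shape[0]

    @property
    def n_steps(self) -> int:
        if self.data.ndim != 3:
            raise ConfigError("time axis absent on a single slice")
        return self.data.shape[1]

    @property
    def n_components(self) -> int:
        return self.data.shape[-1]


@dataclass(frozen=True)
class SimClock:
    """Fixed-step simulation clock: step size ``dt`` and step count."""

    dt: float
    n_steps: int

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ConfigError(f"dt must be positive, got {self.dt}")
        if int(self.n_steps) < 1:
            raise ConfigError(f"n_steps must be >= 1, got {self.n_steps}")

    @property
    def duration(self) -> float:
        return self.dt * self.n_steps


def substream(seed: int, *keys) -> np.random.Generator:
    """Derive an independent, reproducible random stream from (seed, keys).

    Substreams are keyed by stable CRC32 hashes of the string form of each
    key, so e.g. adding a monitor or reordering unrelated groups never
    perturbs the draws of another group.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(str(k).encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def resolve_param(
    spec,
    batch_size: int,
    shape: Sequence[int],
    rng: np.random.Generator,
    *,
    group: str = "?",
    name: str = "?",
) -> np.ndarray | float:
    """Resolve a parameter specification into a concrete array (or scalar).

    ``spec`` may be a scalar, an array(-like), or a *generator function*
    called exactly once as ``spec(batch_size, shape, rng)``; the result must
    broadcast unambiguously to ``[batch_size, *shape]``.
    """
    if batch_size < 1:
        raise ConfigError(f"batch_size must be >= 1, got {batch_size}")
    shape = tuple(int(s) for s in shape)
    if callable(spec):
        value = spec(batch_size, shape, rng)
    else:
        value = spec
    if np.isscalar(value):
        return float(value)
    value = np.asarray(value, dtype=float)
    try:
        np.broadcast_shapes(value.shape, (batch_size, *shape))
    except ValueError as exc:
        raise ParameterShapeError(
            f"group {group!r}, parameter {name!r}: resolved shape "
            f"{value.shape} does not broadcast to {(batch_size, *shape)}"
        ) from exc
    return value


class Model:
    """Base class for group models (neurons, synapses, wrappers).

    Subclasses set :attr:`state_vars` (monitorable state attribute names),
    :attr:`spiking` and :attr:`is_synapse`, and implement the lifecycle
    trio.  ``advance_timestep`` must have no side effects beyond its own
    state.
    """

    state_vars: tuple[str, ...] = ()
    spiking: bool = False
    is_synapse: bool = False

    def __init__(self, n: int):
        if int(n) < 1:
            raise ConfigError(f"component count must be >= 1, got {n}")
        self.n = int(n)
        self.n_in = int(n)
        self.n_out = int(n)
        self.dt: float | None = None
        self.batch_size: int | None = None
        self.dtype = np.float64

    # -- lifecycle ---------------------------------------------------------
    def time_dep(self, dt: float) -> None:
        """Cache dt-dependent constants; must be idempotent for equal dt."""
        if not dt > 0:
            raise ConfigError(f"dt must be positive, got {dt}")
        self.dt = float(dt)

    def set_initial_state(self, batch_size: int) -> None:
        if self.dt is None:
            raise LifecycleError("time_dep must run before set_initial_state")
        if int(batch_size) < 1:
            raise ConfigError(f"batch_size must be >= 1, got {batch_size}")
        self.batch_size = int(batch_size)

    def advance_timestep(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # -- helpers -----------------------------------------------------------
    def _require_state(self) -> None:
        if self.batch_size is None:
            raise LifecycleError(
                f"{type(self).__name__}: advance_timestep called before "
                "time_dep/set_initial_state"
            )

    def monitorable(self) -> tuple[str, ...]:
        return self.state_vars + ("out",)


class InputModel(Model):
    """Pass-through source group: forwards the externally supplied raster."""

    spiking = True  # carries whatever the user injects, typically spikes

    def advance_timestep(self, x: np.ndarray) -> np.ndarray:
        self._require_state()
        x = np.asarray(x, dtype=self.dtype)
        if x.shape[-1] != self.n:
            raise WiringError(
                f"input group expects {self.n} components, got {x.shape[-1]}"
            )
        return x
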