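"""Synthetic dataset generators and demonstration fixtures.

These emulate the structure of the experimental datasets the toolkit
targets — rate-coded spike trains whose class identity lives in the
channel-rate structure (spoken-command-like), and smooth multichannel
sensor sweeps with class-dependent spatial signatures (tactile-array-like)
— so every pipeline stage can be exercised without downloads.  Classes are
decodable by construction; none of the generators claims the statistics of
the real recordings.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import ConfigError, SimClock, substream
from .encode import AnalogTrace
from .network import NetworkGraph

__all__ = [
    "gen_rate_classes",
    "gen_sensor_sweep",
    "train_test_split",
    "demo_three_input_fixture",
]


def gen_rate_classes(
    n_classes: int = 3,
    n_channels: int = 20,
    T: int = 100,
    dt: float = 1.0,
    n_per_class: int = 40,
    rate_profiles: np.ndarray | None = None,
    active_rate: float = 200.0,
    base_rate: float = 10.0,
    seed: int = 0,
):
    """Generate a labeled rate-coded spike-raster dataset.

    Each class drives a distinct block of channels at ``active_rate`` Hz
    while the rest tick at ``base_rate`` Hz; Bernoulli spikes are drawn per
    step with probability ``rate * dt`` (dt in ms).  A custom
    ``rate_profiles`` array ``[n_classes, n_channels]`` (Hz) overrides the
    block structure.  Returns ``(X [N, T, C], y [N])``.
    """
    if rate_profiles is None:
        block = n_channels // n_classes
        if block < 1:
            raise ConfigError("need at least one channel per class")
        rate_profiles = np.full((n_classes, n_channels), base_rate)
        for c in range(n_classes):
            rate_profiles[c, c * block:(c + 1) * block] = active_rate
    else:
        rate_profiles = np.asarray(rate_profiles, dtype=float)
        if rate_profiles.shape != (n_classes, n_channels):
            raise ConfigError("rate_profiles must be [n_classes, n_channels]")
    if len({tuple(r) for r in rate_profiles}) < n_classes:
        warnings.warn("identical rate profiles: classes are not decodable",
                      stacklevel=2)

    p = np.clip(rate_profiles * dt * 1e-3, 0.0, 1.0)
    rng = substream(seed, "gen_rate_classes")
    X = np.zeros((n_classes * n_per_class, T, n_channels))
    y = np.repeat(np.arange(n_classes), n_per_class)
    for i, label in enumerate(y):
        X[i] = (rng.random((T, n_channels)) < p[label][None, :]).astype(float)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


def gen_sensor_sweep(
    n_classes: int = 3,
    n_sensors: int = 28,
    T_raw: int = 28,
    n_per_class: int = 20,
    noise: float = 0.02,
    seed: int = 0,
):
    """Generate analog sensor-sweep traces with class-dependent spatial
    bump patterns traversed in time (tactile-array-like structure).

    Each sample is an :class:`AnalogTrace` with ``[n_sensors, T_raw]``
    values: a Gaussian spatial bump whose center follows a class-specific
    trajectory across the array, plus i.i.d. Gaussian noise.  Returns
    ``(traces, y)``.
    """
    rng = substream(seed, "gen_sensor_sweep")
    sensors = np.arange(n_sensors)[:, None]  # [C, 1]
    time = np.linspace(0.0, 1.0, T_raw)[None, :]  # [1, T]
    traces, labels = [], []
    for c in range(n_classes):
        start = n_sensors * (0.15 + 0.6 * c / max(n_classes - 1, 1))
        slope = n_sensors * (0.25 if c % 2 == 0 else -0.25)
        width = 2.0 + 0.5 * c
        for _ in range(n_per_class):
            jitter = rng.normal(0.0, 0.5)
            center = start + jitter + slope * time  # [1, T]
            bump = np.exp(-0.5 * ((sensors - center) / width) ** 2)
            bump = bump + rng.normal(0.0, noise, size=bump.shape)
            traces.append(AnalogTrace(values=bump))
            labels.append(c)
    y = np.asarray(labels)
    perm = rng.permutation(len(y))
    return [traces[i] for i in perm], y[perm]


def train_test_split(X, y, test_frac: float = 0.15, seed: int = 0):
    """Seeded shuffled split; default hold-out fraction 15%."""
    if not (0 < test_frac < 1):
        raise ConfigError("test_frac must be in (0, 1)")
    n = len(y)
    rng = substream(seed, "train_test_split")
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_frac)))
    test, train = perm[:n_test], perm[n_test:]
    if isinstance(X, np.ndarray):
        return X[train], y[train], X[test], y[test]
    return ([X[i] for i in train], y[train],
            [X[i] for i in test], y[test])


def demo_three_input_fixture(T: int = 100, n_batches: int = 10, seed: int = 0):
    """The small demonstration network: 3 input neurons feeding a single
    LIF output neuron through a 3-synapse leaky group.

    The LIF membrane time constant is supplied as a generator function
    sweeping 10 ms to 100 ms in 10 ms steps across the ``n_batches``
    parallel simulations, so one run exposes the parameter dependence of
    the membrane response.  Returns ``(network, clock, input_raster)`` with
    the raster shaped ``[n_batches, T, 3]`` (identical across batches).
    """

    def tau_sweep(batch_size, shape, rng):
        taus = 10.0 * (np.arange(batch_size) + 1)
        return taus[:, None] * np.ones((1,) + tuple(shape))

    net = NetworkGraph()
    net.add("input", "in", 3)
    net.add("lif", "out", 1, tau=tau_sweep, theta=3.0)
    net.add("ls", "syn", source="in", target="out", tau=8.0, w=0.5)
    net.set_ports("in", "out")

    rng = substream(seed, "demo_raster")
    raster = np.zeros((T, 3))
    for c, period in enumerate((7, 11, 17)):
        raster[c::period, c] = 1.0
    # sparse extra spikes to break the periodicity
    raster += (rng.random((T, 3)) < 0.02)
    raster = np.clip(raster, 0.0, 1.0)
    x = np.broadcast_to(raster[None, :, :], (n_batches, T, 3)).copy()
    return net, SimClock(dt=1.0, n_steps=T), x
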