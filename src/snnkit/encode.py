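"""Analog-to-spike encoders: rate coding, delta modulation, spline upscaling.

Conventions: analog traces are ``[channels, samples]`` arrays with uniform
sample spacing; encoded rasters follow the ``[batch, time, components]``
signal convention.  Rates are expressed in Hz with ``dt`` in milliseconds
(the one place a unit convention is baked in, documented here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .core import ConfigError, SignalTensor, substream

__all__ = [
    "AnalogTrace",
    "EncoderConfig",
    "rate_encode",
    "spline_upscale",
    "delta_encode",
]


@dataclass
class AnalogTrace:
    """Multichannel analog signal: ``values`` is ``[channels, samples]``."""

    values: np.ndarray
    sample_spacing: float = 1.0

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("analog trace contains non-finite values")
        if self.values.shape[1] < 2:
            raise ConfigError("analog trace needs at least 2 samples")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class EncoderConfig:
    """Encoder settings.

    mode : "rate" | "delta_bipolar" | "delta_thermometer"
    threshold_frac : rate mode — intensities at or below this fraction of
        the dynamic range produce no spikes (default 0.2)
    f_max : rate mode — rate in Hz at full intensity (default 500)
    delta : delta modes — modulation step in signal units
    levels : thermometer mode — graded channels per input channel
    dt : time-step in ms; T : raster length in steps
    regular : rate mode — deterministic evenly spaced spikes instead of
        the default Bernoulli (Poisson-like) process
    """

    mode: str = "rate"
    threshold_frac: float = 0.2
    f_max: float = 500.0
    delta: float = 0.01
    levels: int = 3
    dt: float = 1.0
    T: int = 100
    regular: bool = False

    def __post_init__(self):
        if self.mode not in ("rate", "delta_bipolar", "delta_thermometer"):
            raise ConfigError(f"unknown encoder mode {self.mode!r}")
        if not (0 <= self.threshold_frac < 1):
            raise ConfigError("threshold_frac must be in [0, 1)")
        if self.f_max <= 0:
            raise ConfigError("f_max must be positive")
        if self.delta <= 0:
            raise ConfigError("delta must be positive")
        if self.levels < 1:
            raise ConfigError("levels must be >= 1")


def rate_encode(x, cfg: EncoderConfig, seed: int = 0) -> SignalTensor:
    """Thresholded linear intensity-to-rate spike encoding.

    Intensities ``x`` in [0, 1] (one value per channel) map to rates: zero
    at or below ``threshold_frac`` of the dynamic range, then linearly up
    to ``f_max`` Hz at full intensity.  Spikes are drawn per step as a
    Bernoulli process with probability ``rate * dt`` (dt in ms), clamped to
    1 with a saturation warning.  Returns a ``[1, T, C]`` spike tensor.
    """
    if cfg.mode != "rate":
        raise ConfigError("rate_encode requires cfg.mode == 'rate'")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    thr = cfg.threshold_frac
    rate = np.where(x <= thr, 0.0, (x - thr) / (1.0 - thr) * cfg.f_max)
    p = rate * cfg.dt * 1e-3
    if np.any(p > 1):
        warnings.warn("rate * dt exceeds 1: spike probability saturated",
                      stacklevel=2)
        p = np.minimum(p, 1.0)
    if cfg.regular:
        steps = np.arange(cfg.T)[:, None]
        # deterministic evenly spaced spikes at the same mean rate
        phase = (steps + 1) * p[None, :]
        raster = (np.floor(phase) > np.floor(phase - p[None, :])).astype(float)
    else:
        rng = substream(seed, "rate_encode")
        raster = (rng.random((cfg.T, x.size)) < p[None, :]).astype(float)
    return SignalTensor.spikes(raster[None, :, :])


def spline_upscale(trace: AnalogTrace, T_out: int) -> AnalogTrace:
    """Upscale the temporal resolution of a trace by cubic-spline
    interpolation onto ``T_out`` uniformly spaced samples (endpoints are
    preserved exactly).  Traces with fewer than 4 samples fall back to
    linear interpolation with a warning."""
    if T_out < trace.n_samples:
        raise ConfigError(
            f"T_out={T_out} below the original {trace.n_samples} samples"
        )
    t_in = np.linspace(0.0, 1.0, trace.n_samples)
    t_out = np.linspace(0.0, 1.0, T_out)
    if trace.n_samples < 4:
        warnings.warn("fewer than 4 samples: falling back to linear "
                      "interpolation", stacklevel=2)
        values = np.vstack([
            np.interp(t_out, t_in, row) for row in trace.values
        ])
    else:
        values = CubicSpline(t_in, trace.values, axis=1)(t_out)
    spacing = trace.sample_spacing * (trace.n_samples - 1) / (T_out - 1)
    return AnalogTrace(values=values, sample_spacing=spacing)


def delta_encode(trace: AnalogTrace, cfg: EncoderConfig) -> SignalTensor:
    """Delta-modulation spike encoding of an analog trace.

    ``delta_bipolar`` tracks each channel with an accumulator initialized
    at the channel's first sample: an UP spike is emitted when the signal
    exceeds the accumulator by ``delta`` (accumulator += delta) and a DOWN
    spike on the symmetric fall, giving ``2C`` output channels (first C:
    UP, last C: DOWN).  ``delta_thermometer`` emits on ``levels`` graded
    channels per input channel: channel m (1-based) spikes when the
    per-step change magnitude reaches ``m * delta``, giving ``levels * C``
    output channels.  Both modes are invariant to a constant signal offset.
    """
    x = trace.values  # [C, T]
    C, T = x.shape
    if cfg.mode == "delta_bipolar":
        up = np.zeros((T, C))
        down = np.zeros((T, C))
        acc = x[:, 0].copy()
        for t in range(T):
            rise = x[:, t] >= acc + cfg.delta
            fall = x[:, t] <= acc - cfg.delta
            up[t] = rise.astype(float)
            down[t] = fall.astype(float)
            acc = acc + cfg.delta * rise - cfg.delta * fall
        raster = np.concatenate([up, down], axis=1)  # [T, 2C]
    elif cfg.mode == "delta_thermometer":
        change = np.abs(np.diff(x, axis=1, prepend=x[:, :1]))  # [C, T]
        k = cfg.levels
        thresholds = cfg.delta * np.arange(1, k + 1)  # [k]
        # [T, C, k] -> [T, C*k]
        graded = (change.T[:, :, None] >= thresholds[None, None, :])
        raster = graded.reshape(T, C * k).astype(float)
    else:
        raise ConfigError("delta_encode requires a delta_* mode")
    return SignalTensor.spikes(raster[None, :, :])
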