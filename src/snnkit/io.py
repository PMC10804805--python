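"""Array I/O: spike rasters, traces and weight matrices.

Rasters and traces travel as compressed ``.npz`` archives (arrays keyed by
name plus a ``dt`` scalar) or as CSV — one row per time-step, one column
per component, with the time-step size recorded in the header comment.
Weight matrices load/store as CSV or ``.npz``.
"""

from __future__ import annotations

import numpy as np

from .core import ConfigError

__all__ = [
    "save_raster",
    "load_raster",
    "save_raster_csv",
    "load_raster_csv",
    "save_weights",
    "load_weights",
]


def save_raster(path, data: np.ndarray, dt: float = 1.0, **extra) -> None:
    """Save a ``[B, T, C]`` (or ``[T, C]``) array with its dt to ``.npz``."""
    np.savez_compressed(path, data=np.asarray(data), dt=float(dt), **extra)


def load_raster(path):
    """Load an ``.npz`` raster; returns ``(data, dt)``."""
    with np.load(path) as archive:
        return archive["data"], float(archive["dt"])


def save_raster_csv(path, data: np.ndarray, dt: float = 1.0) -> None:
    """Save a single-sample ``[T, C]`` raster as CSV (dt in the header)."""
    data = np.asarray(data)
    if data.ndim == 3:
        if data.shape[0] != 1:
            raise ConfigError("CSV rasters hold one sample; use .npz for "
                              "batched data")
        data = data[0]
    header = f"dt={dt}\n" + ",".join(f"c{i}" for i in range(data.shape[1]))
    np.savetxt(path, data, delimiter=",", header=header, comments="# ")


def load_raster_csv(path):
    """Load a CSV raster written by :func:`save_raster_csv`;
    returns ``([T, C] array, dt)``."""
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# dt="):
        raise ConfigError(f"{path}: missing '# dt=' header")
    dt = float(first.split("=", 1)[1])
    data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    return data, dt


def save_weights(path, w: np.ndarray) -> None:
    """Save a weight matrix (.npz for str(path) ending '.npz', else CSV)."""
    w = np.asarray(w, dtype=float)
    if str(path).endswith(".npz"):
        np.savez_compressed(path, w=w)
    else:
        np.savetxt(path, w, delimiter=",")


def load_weights(path) -> np.ndarray:
    """Load a weight matrix saved by :func:`save_weights`."""
    if str(path).endswith(".npz"):
        with np.load(path) as archive:
            return archive["w"]
    return np.loadtxt(path, delimiter=",", ndmin=2)
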