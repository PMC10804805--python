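"""Post-training hardware non-ideality analysis.

Two mechanisms of memristive weight storage are emulated on trained
networks: *quantization* onto a finite set of equidistant, symmetric,
signed conductance levels with a stochastic write error, and *conductance
drift* — a time-dependent power-law relaxation of stored weight
magnitudes.  Sweep harnesses re-evaluate classification accuracy under
repeated random draws and report summary statistics.

The write-error scale follows the 3-sigma level-crossing rule: adjacent
level distributions (spacing ``delta``) cross at three standard deviations
from each mean, i.e. ``sigma = delta / 6``; the probability mass falling
past the crossing point is then ``2 * Phi(-3) ~= 0.27%`` (approximately
the 0.3% overlap characteristic of measured memristor conductance
distributions).

The drift law ``w(t) = w0 * (t / t0)**(-nu)`` with per-weight exponents
``nu ~ Normal(nu_mean, nu_sigma)`` truncated at zero is a parameterized
stand-in for device-specific drift compact models; signs are preserved and
magnitudes are non-increasing in time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import ConfigError, substream

__all__ = [
    "QuantizerSpec",
    "DriftSpec",
    "level_overlap_fraction",
    "quantize_weights",
    "drift_weights",
    "sweep_quantization",
    "sweep_drift",
]


@dataclass
class QuantizerSpec:
    """Equidistant symmetric signed quantizer.

    ``n_levels`` (or ``bits``, with ``n_levels = 2**bits``) levels span
    ``[-w_max, +w_max]``; ``w_max`` defaults to ``max|w|`` of the quantized
    matrix.  ``noise=True`` adds the Gaussian write error with
    ``sigma = spacing / 6`` (3-sigma crossing)."""

    n_levels: int | None = None
    bits: int | None = None
    w_max: float | None = None
    noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_levels is None:
            if self.bits is None:
                raise ConfigError("provide n_levels or bits")
            self.n_levels = 2 ** int(self.bits)
        if self.n_levels < 2:
            raise ConfigError("n_levels must be >= 2")


@dataclass
class DriftSpec:
    """Power-law conductance drift: ``|w|(t) = |w0| * (t/t0)**(-nu)`` with
    per-weight ``nu ~ Normal(nu_mean, nu_sigma)`` truncated at 0."""

    nu_mean: float = 0.1
    nu_sigma: float = 0.0
    t0: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.t0 <= 0:
            raise ConfigError("reference time t0 must be positive")
        if self.nu_sigma < 0:
            raise ConfigError("nu_sigma must be >= 0")


def level_overlap_fraction() -> float:
    """Fraction of a level's write distribution falling past the crossing
    point with either neighbor under the 3-sigma rule: ``2 * Phi(-3)``."""
    return float(2.0 * norm.cdf(-3.0))


def quantize_weights(w: np.ndarray, spec: QuantizerSpec) -> np.ndarray:
    """Snap weights to the nearest of ``n_levels`` equidistant levels over
    ``[-w_max, +w_max]``, then (optionally) perturb each stored value with
    the seeded Gaussian write error ``sigma = spacing / 6``."""
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ConfigError("weights must be finite")
    w_max = spec.w_max if spec.w_max is not None else float(np.max(np.abs(w)))
    if w_max == 0:
        warnings.warn("all-zero weight matrix: quantization is a no-op",
                      stacklevel=2)
        return w.copy()
    levels = np.linspace(-w_max, w_max, spec.n_levels)
    spacing = 2.0 * w_max / (spec.n_levels - 1)
    idx = np.argmin(np.abs(w[..., None] - levels), axis=-1)
    w_q = levels[idx]
    if spec.noise:
        rng = substream(spec.seed, "quantize")
        w_q = w_q + rng.normal(0.0, spacing / 6.0, size=w_q.shape)
    return w_q


def drift_weights(w: np.ndarray, t_elapsed: float,
                  spec: DriftSpec) -> np.ndarray:
    """Apply power-law magnitude drift for a storage time ``t_elapsed``
    (measured from the reference time ``t0``); signs are preserved."""
    if t_elapsed < spec.t0:
        raise ConfigError(
            f"t_elapsed={t_elapsed} precedes the reference time t0={spec.t0}"
        )
    w = np.asarray(w, dtype=float)
    rng = substream(spec.seed, "drift")
    nu = rng.normal(spec.nu_mean, spec.nu_sigma, size=w.shape) \
        if spec.nu_sigma > 0 else np.full(w.shape, spec.nu_mean)
    nu = np.maximum(nu, 0.0)  # truncation at zero: no spontaneous growth
    factor = (t_elapsed / spec.t0) ** (-nu)
    return np.sign(w) * np.abs(w) * factor


def _eval_with_weights(model, X, y, replacements: dict) -> float:
    """Evaluate accuracy with temporarily substituted weight matrices."""
    from .train import evaluate

    saved = {g: model.get_weights(g) for g in replacements}
    try:
        for g, w in replacements.items():
            model.set_weights(g, w)
        acc, _ = evaluate(model, X, y)
    finally:
        for g, w in saved.items():
            model.set_weights(g, w)
    return acc


def sweep_quantization(model, X, y, group_ids, bits_list, trials: int = 5,
                       seed: int = 0) -> pd.DataFrame:
    """Accuracy vs quantization bit-width.

    For each bit-width, ``trials`` independent noisy quantizations of the
    listed weight groups are evaluated; returns a table with mean, min and
    max accuracy per row.  A non-monotone mean across decreasing bit-widths
    is logged as a warning (sampling noise aside, coarser storage should
    not help)."""
    if not list(bits_list):
        raise ConfigError("bits_list must not be empty")
    rows = []
    for bits in bits_list:
        accs = []
        for trial in range(trials):
            trial_seed = substream(seed, "qsweep", bits, trial).integers(2**31)
            reps = {
                g: quantize_weights(
                    model.get_weights(g),
                    QuantizerSpec(bits=bits, seed=trial_seed),
                )
                for g in group_ids
            }
            accs.append(_eval_with_weights(model, X, y, reps))
        rows.append({"bits": int(bits), "acc_mean": float(np.mean(accs)),
                     "acc_min": float(np.min(accs)),
                     "acc_max": float(np.max(accs))})
    table = pd.DataFrame(rows)
    ordered = table.sort_values("bits", ascending=False)["acc_mean"].to_numpy()
    if np.any(np.diff(ordered) > 0.05):
        warnings.warn("quantization sweep is not monotone-degrading beyond "
                      "trial error", stacklevel=2)
    return table


def sweep_drift(model, X, y, group_ids, times, spec: DriftSpec | None = None,
                iterations: int = 20, seed: int = 0) -> pd.DataFrame:
    """Accuracy vs storage time under conductance drift.

    For each elapsed time, ``iterations`` random draws of the per-weight
    drift exponents are evaluated; returns mean and standard deviation per
    row.  Drift starts from the unquantized trained weights (write-verify
    storage assumed)."""
    spec = spec or DriftSpec()
    rows = []
    for t in times:
        accs = []
        for it in range(iterations):
            it_seed = substream(seed, "dsweep", t, it).integers(2**31)
            it_spec = DriftSpec(nu_mean=spec.nu_mean, nu_sigma=spec.nu_sigma,
                                t0=spec.t0, seed=it_seed)
            reps = {
                g: drift_weights(model.get_weights(g), t, it_spec)
                for g in group_ids
            }
            accs.append(_eval_with_weights(model, X, y, reps))
        rows.append({"t": float(t), "acc_mean": float(np.mean(accs)),
                     "acc_std": float(np.std(accs))})
    return pd.DataFrame(rows)
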