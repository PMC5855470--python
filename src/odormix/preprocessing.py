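"""Affine input/output normalization fitted on the learning partition only.

Network inputs are z-scored per channel (centering followed by division by
the per-channel population standard deviation); the single regression output
is likewise z-scored during training and inverted at prediction time so that
quality indicators are comparable to the one-unit spacing of the verbal
scale classes. Statistics must come from the learning(+validation) samples,
never from the held-out test phase — the fitting functions only see the
arrays the model-selection layer hands them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError, FitError

log = logging.getLogger(__name__)

_DEGENERATE_SCALE = 1e-12


@dataclass(frozen=True)
class NormalizerParams:
    means: tuple  # per-channel mean
    scales: tuple  # per-channel population SD (degenerate channels forced to 1)
    fitted_on: int
    degenerate: tuple = ()  # indices of channels whose SD was forced to 1


@dataclass(frozen=True)
class OutputScalerParams:
    mean: float
    scale: float
    target_name: str  # {"OI", "HT"}


def fit_input_normalizer(vectors) -> NormalizerParams:
    """Per-channel mean/SD over the learning+validation sensor vectors."""
    X = _as_matrix(vectors)
    if X.shape[0] < 2:
        raise FitError("need at least 2 vectors to fit the input normalizer")
    means = X.mean(axis=0)
    scales = X.std(axis=0)  # population SD
    degenerate = np.flatnonzero(scales < _DEGENERATE_SCALE)
    if degenerate.size:
        log.warning(
            "channels %s have (near-)zero variance; scale forced to 1", list(degenerate)
        )
        scales = scales.copy()
        scales[degenerate] = 1.0
    return NormalizerParams(
        means=tuple(float(m) for m in means),
        scales=tuple(float(s) for s in scales),
        fitted_on=int(X.shape[0]),
        degenerate=tuple(int(i) for i in degenerate),
    )


def apply_normalizer(params: NormalizerParams, vectors) -> np.ndarray:
    """(x - mean) / scale, vector- or matrix-valued."""
    X = np.asarray(_strip(vectors), dtype=float)
    if X.shape[-1] != len(params.means):
        raise DataError(
            f"vector length {X.shape[-1]} does not match normalizer ({len(params.means)})"
        )
    return (X - np.asarray(params.means)) / np.asarray(params.scales)


def invert_normalizer(params: NormalizerParams, normalized) -> np.ndarray:
    X = np.asarray(normalized, dtype=float)
    return X * np.asarray(params.scales) + np.asarray(params.means)


def identity_normalizer(n_channels: int = 8) -> NormalizerParams:
    return NormalizerParams(
        means=(0.0,) * n_channels, scales=(1.0,) * n_channels, fitted_on=2
    )


def fit_output_scaler(targets, target_name: str) -> OutputScalerParams:
    y = np.asarray(targets, dtype=float)
    if y.size < 2:
        raise FitError("need at least 2 targets to fit the output scaler")
    scale = float(y.std())
    if scale < _DEGENERATE_SCALE:
        log.warning("target '%s' has (near-)zero variance; scale forced to 1", target_name)
        scale = 1.0
    return OutputScalerParams(mean=float(y.mean()), scale=scale, target_name=target_name)


def scale_output(params: OutputScalerParams, y, direction: str = "forward"):
    """Forward: (y - mean)/scale; inverse: y*scale + mean."""
    y = np.asarray(y, dtype=float)
    if direction == "forward":
        out = (y - params.mean) / params.scale
    elif direction == "inverse":
        out = y * params.scale + params.mean
    else:
        raise DataError(f"unknown direction: {direction!r}")
    return float(out) if out.ndim == 0 else out


def identity_output_scaler(target_name: str = "OI") -> OutputScalerParams:
    return OutputScalerParams(mean=0.0, scale=1.0, target_name=target_name)


def _strip(vectors):
    """Accept SensorVector objects, arrays, or sequences thereof."""
    if hasattr(vectors, "as_array"):
        return vectors.as_array()
    if isinstance(vectors, (list, tuple)) and vectors and hasattr(vectors[0], "as_array"):
        return np.stack([v.as_array() for v in vectors])
    return vectors


def _as_matrix(vectors) -> np.ndarray:
    X = np.asarray(_strip(vectors), dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X
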