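"""PCA loading analysis of the sensor channels.

Loadings come from the eigen-decomposition of the channel correlation
matrix (channels carry wildly different units, so variables are
standardized), scaled by the square root of the eigenvalues. On a biplot
the angle between two loading vectors reads as correlation: near 0 degrees
strongly positive, near 180 strongly negative, near 90 independent. A
channel's contribution to a component is the absolute value of its loading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .synthetic import CHANNELS

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LoadingSet:
    loadings: np.ndarray  # 8 x K, channels by components
    explained_variance_ratio: tuple
    channel_names: tuple

    def __post_init__(self):
        evr = np.asarray(self.explained_variance_ratio)
        if (evr < -1e-12).any() or np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
            raise DataError("explained variance ratios must be nonnegative, non-increasing, sum <= 1")


def compute_pca_loadings(sensor_matrix, n_components: int = 2, channel_names=CHANNELS) -> LoadingSet:
    """Correlation-matrix PCA loadings with a deterministic sign convention."""
    X = np.asarray(sensor_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < X.shape[1]:
        raise DataError("need an n x p matrix with n >= p")
    p = X.shape[1]
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise DataError("constant channel: correlation undefined")
    corr = np.corrcoef(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    rank = int(np.sum(eigvals > 1e-10))
    k = min(n_components, rank)
    if k < n_components:
        log.warning("rank-deficient input: reporting %d components instead of %d", k, n_components)
    loadings = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    # sign convention: the largest-magnitude entry of each component positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] = -loadings[:, j]
    evr = eigvals[:k] / eigvals.sum()
    return LoadingSet(
        loadings=loadings,
        explained_variance_ratio=tuple(float(v) for v in evr),
        channel_names=tuple(channel_names[:p]),
    )


def loading_angle(v1, v2) -> float:
    """Angle in degrees between two loading vectors (0..180)."""
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DataError("angle undefined for a zero vector")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def rank_sensor_contributions(loadings: LoadingSet, component: int = 0) -> list:
    """Channels sorted by |loading| on one component, descending.

    Ties break on channel name so the ordering is reproducible. Returns
    (channel_name, signed_loading) pairs.
    """
    L = loadings.loadings
    if component >= L.shape[1]:
        raise DataError(f"component {component} not available (K={L.shape[1]})")
    col = L[:, component]
    order = sorted(
        range(len(col)), key=lambda i: (-abs(col[i]), loadings.channel_names[i])
    )
    return [(loadings.channel_names[i], float(col[i])) for i in order]
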