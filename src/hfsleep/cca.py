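"""Canonical correlation analysis for two-channel feature fusion.

Given per-epoch feature matrices from two EEG channels, CCA finds paired
linear projections maximizing the correlation between the projected views
under unit-variance and cross-direction orthogonality constraints.  The
fused representation is the concatenation of the two projected views —
channel-specific information is preserved rather than averaged away.

Solved by whitening: with ridge-stabilized covariances ``Cxx, Cyy`` the
singular values of ``Cxx^{-1/2} Cxy Cyy^{-1/2}`` are the canonical
correlations and its singular vectors, back-rotated through the whitening,
the projection weights.  The ridge handles rank-deficient views explicitly;
dimensions are never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg


@dataclass
class CCAProjection:
    """Fitted canonical maps for two views.

    ``x_weights``/``y_weights`` project centered views onto ``k`` canonical
    directions; ``correlations`` are the per-direction canonical
    correlations (non-increasing, in [0, 1] up to numerical tolerance).
    Centering always uses the means stored at fit time (the training set).
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    correlations: np.ndarray
    reg: float

    @property
    def k(self) -> int:
        return self.x_weights.shape[1]


def _cov_blocks(x: np.ndarray, y: np.ndarray, reg: float):
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    cxx = xc.T @ xc / (n - 1)
    cyy = yc.T @ yc / (n - 1)
    cxy = xc.T @ yc / (n - 1)
    # relative ridge: scaled by the mean variance of each view
    rx = reg * max(np.trace(cxx) / cxx.shape[0], 1e-30)
    ry = reg * max(np.trace(cyy) / cyy.shape[0], 1e-30)
    cxx = cxx + rx * np.eye(cxx.shape[0])
    cyy = cyy + ry * np.eye(cyy.shape[0])
    return cxx, cyy, cxy


def _inv_sqrt(c: np.ndarray) -> np.ndarray:
    w, v = linalg.eigh(c)
    w = np.clip(w, 1e-30, None)
    return (v / np.sqrt(w)) @ v.T


def fit_cca(
    view1: np.ndarray,
    view2: np.ndarray,
    k: int,
    reg: float = 1e-4,
) -> CCAProjection:
    """Fit ridge-regularized CCA between two equal-row-count views.

    The per-direction sign is fixed by making the largest-magnitude loading
    of each ``view1`` weight vector positive, so refits are deterministic.
    """
    x = np.asarray(view1, dtype=float)
    y = np.asarray(view2, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("views must be 2-D with equal row counts")
    n = x.shape[0]
    if k > min(x.shape[1], y.shape[1]):
        raise ValueError(
            f"k={k} exceeds the smaller view dimension {min(x.shape[1], y.shape[1])}"
        )
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} rows, got {n}")

    cxx, cyy, cxy = _cov_blocks(x, y, reg)
    wx_isqrt = _inv_sqrt(cxx)
    wy_isqrt = _inv_sqrt(cyy)
    u, s, vt = linalg.svd(wx_isqrt @ cxy @ wy_isqrt, full_matrices=False)
    wx = wx_isqrt @ u[:, :k]
    wy = wy_isqrt @ vt[:k].T
    rho = s[:k]

    for j in range(k):
        i_max = int(np.argmax(np.abs(wx[:, j])))
        if wx[i_max, j] < 0:
            wx[:, j] = -wx[:, j]
            wy[:, j] = -wy[:, j]

    return CCAProjection(
        x_mean=x.mean(axis=0),
        y_mean=y.mean(axis=0),
        x_weights=wx,
        y_weights=wy,
        correlations=rho,
        reg=reg,
    )


def apply_cca(
    projection: CCAProjection, view1: np.ndarray, view2: np.ndarray
) -> np.ndarray:
    """Project both views and concatenate: ``(n, 2k)`` fused features.

    Centering uses the training-set means stored in the projection, never
    the statistics of the data being transformed.
    """
    x = np.asarray(view1, dtype=float)
    y = np.asarray(view2, dtype=float)
    if x.shape[1] != projection.x_mean.size or y.shape[1] != projection.y_mean.size:
        raise ValueError(
            f"view dimensions ({x.shape[1]}, {y.shape[1]}) do not match the "
            f"fitted maps ({projection.x_mean.size}, {projection.y_mean.size})"
        )
    fx = (x - projection.x_mean) @ projection.x_weights
    fy = (y - projection.y_mean) @ projection.y_weights
    return np.hstack([fx, fy])
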