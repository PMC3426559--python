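"""Procrustes superposition of one planar map onto another.

Given a fixed target configuration X (geographic locations) and a moving
configuration Y (PC1-PC2 coordinates), find the similarity transformation
of Y — translation, positive scaling, rotation, optionally reflection —
minimizing the sum of squared Euclidean distances to X while preserving Y's
internal shape.  Similarity is summarized by

    t0 = sqrt(1 - D),    D = minimized SS / tr(X_c' X_c),

so D is scaled to [0, 1] (0 = exact similarity-transform match) and t0 to
[0, 1] with 1 = exact match.  The closed-form solution comes from the SVD of
the 2x2 cross-covariance of the centered configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ProcrustesFit", "procrustes_fit", "superimpose"]


@dataclass
class ProcrustesFit:
    """Optimal similarity transformation of a moving map onto a target.

    ``rotation_deg`` is the counterclockwise rotation angle in (-180, 180].
    When ``reflection_used`` the orthogonal part is factored as
    (reflection across the first axis) followed by that rotation.
    ``transformed`` is the moving configuration after the full transformation.
    """

    t0: float
    D: float
    rotation_deg: float
    reflection_used: bool
    scale: float
    translation: np.ndarray   # (2,)
    rotation_matrix: np.ndarray  # (2, 2) orthogonal, applied to row vectors
    transformed: np.ndarray   # (n, 2)


def _angle_deg(Q: np.ndarray) -> float:
    """CCW rotation angle of a row-vector rotation matrix, in (-180, 180]."""
    theta = math.degrees(math.atan2(Q[0, 1], Q[0, 0]))
    if theta <= -180.0:
        theta += 360.0
    return 180.0 if theta == -180.0 else theta


def procrustes_fit(X_target: np.ndarray, Y_moving: np.ndarray,
                   allow_reflection: bool = True) -> ProcrustesFit:
    """Fit the optimal similarity transformation of ``Y_moving`` onto
    ``X_target`` and return the fit with the similarity statistic t0.

    Both inputs are (n, 2) with n >= 3 and non-zero dispersion.  When
    ``allow_reflection`` is False and the unconstrained optimum is a
    reflection, the best proper rotation is used instead (the smallest
    singular value enters the trace sum with a negative sign).
    """
    X = np.asarray(X_target, dtype=float)
    Y = np.asarray(Y_moving, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X_target and Y_moving must both be (n, 2)")
    n = X.shape[0]
    if n < 3:
        raise ValueError("Procrustes fit needs at least 3 points")
    xbar = X.mean(axis=0)
    ybar = Y.mean(axis=0)
    Xc = X - xbar
    Yc = Y - ybar
    trX = float((Xc ** 2).sum())
    trY = float((Yc ** 2).sum())
    if trX == 0.0 or trY == 0.0:
        raise ValueError("zero-dispersion configuration (all points coincident)")

    A = Yc.T @ Xc
    U, sigma, Vt = np.linalg.svd(A)
    det_sign = np.sign(np.linalg.det(U @ Vt))
    if allow_reflection or det_sign >= 0:
        Q = U @ Vt
        trace_sum = float(sigma.sum())
    else:
        S = np.diag([1.0, -1.0])
        Q = U @ S @ Vt
        trace_sum = float(sigma[0] - sigma[1])
    reflection_used = bool(np.linalg.det(Q) < 0)

    scale = trace_sum / trY
    t0 = trace_sum / math.sqrt(trX * trY)
    t0 = min(max(t0, 0.0), 1.0)
    D = 1.0 - t0 ** 2
    translation = xbar - scale * (ybar @ Q)
    transformed = scale * (Y @ Q) + translation

    if reflection_used:
        # factor Q = F @ R with F = diag(1, -1); report the angle of R
        R = np.diag([1.0, -1.0]) @ Q
    else:
        R = Q
    return ProcrustesFit(
        t0=t0,
        D=D,
        rotation_deg=_angle_deg(R),
        reflection_used=reflection_used,
        scale=scale,
        translation=translation,
        rotation_matrix=Q,
        transformed=transformed,
    )


def superimpose(fit: ProcrustesFit, extra_points: np.ndarray) -> np.ndarray:
    """Apply a fit's stored transformation to auxiliary points (e.g. PC-axis
    endpoints for plotting)."""
    P = np.asarray(extra_points, dtype=float)
    return fit.scale * (P @ fit.rotation_matrix) + fit.translation
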