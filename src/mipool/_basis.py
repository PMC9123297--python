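"""Cubic B-spline basis construction, penalties, and centering constraints."""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

logger = logging.getLogger(__name__)

_DEGREE = 3  # cubic


def quantile_knots(x: np.ndarray, n_interior: int, name: str = "") -> np.ndarray:
    """Interior knots at the equally spaced quantiles of ``x``.

    Coincident knots (possible when x has few distinct values) are
    deduplicated with a log message; the basis dimension shrinks accordingly.
    """
    # a basis wider than the number of distinct values is rank-deficient:
    # cap the interior knots at n_distinct - (degree + 1)
    n_distinct = np.unique(x).size
    cap = max(n_distinct - _DEGREE - 1, 0)
    qs = np.linspace(0.0, 1.0, min(n_interior, cap) + 2)[1:-1]
    knots = np.quantile(x, qs)
    uniq = np.unique(knots)
    lo, hi = float(np.min(x)), float(np.max(x))
    uniq = uniq[(uniq > lo) & (uniq < hi)]
    if uniq.size < n_interior:
        logger.warning(
            "covariate %s: %d interior knots deduplicated/capped to %d "
            "(%d distinct values)",
            name or "<unnamed>", n_interior, uniq.size, n_distinct,
        )
    return uniq


def knot_vector(interior: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Clamped cubic knot vector: boundary knots repeated degree+1 times."""
    return np.r_[[lo] * (_DEGREE + 1), interior, [hi] * (_DEGREE + 1)]


def bspline_design(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Design matrix of all cubic B-splines on knot vector ``t``.

    Values outside the boundary knots (possible when predicting on new data)
    are clamped to the boundary.
    """
    lo, hi = t[_DEGREE], t[-_DEGREE - 1]
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, t, _DEGREE).toarray()


def second_derivative_penalty(t: np.ndarray) -> np.ndarray:
    """Exact integral penalty S[i, j] = int B_i''(u) B_j''(u) du.

    For cubic splines the second derivatives are piecewise linear, so the
    integrand is piecewise quadratic and 3-point Gauss-Legendre per knot
    span is exact.
    """
    n_basis = len(t) - _DEGREE - 1
    spans = np.unique(t)
    # 3-point Gauss-Legendre nodes/weights on [-1, 1]
    gx = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
    gw = np.array([5.0, 8.0, 5.0]) / 9.0
    points, weights = [], []
    for a, b in zip(spans[:-1], spans[1:]):
        half = 0.5 * (b - a)
        points.append(0.5 * (a + b) + half * gx)
        weights.append(half * gw)
    xq = np.concatenate(points)
    wq = np.concatenate(weights)
    D2 = np.empty((len(xq), n_basis))
    eye = np.eye(n_basis)
    for i in range(n_basis):
        D2[:, i] = BSpline(t, eye[i], _DEGREE)(xq, nu=2)
    return D2.T @ (wq[:, None] * D2)


def centering_transform(B: np.ndarray) -> np.ndarray:
    """Null-space basis Z of the sum-to-zero constraint mean(B @ beta) = 0.

    Reparameterizing a smooth's columns as B @ Z removes its confounding
    with the model intercept and drops one basis dimension.
    """
    c = B.mean(axis=0)[None, :]
    Z = null_space(c)
    if Z.shape[1] != B.shape[1] - 1:
        raise np.linalg.LinAlgError("degenerate centering constraint")
    return Z
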