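"""Penalized cubic smoothing splines in the csaps/SMOOTH parameterization.

The fit minimizes, over natural cubic splines f with knots at the data,

    p * sum_j (y_j - f(t_j))^2  +  (1 - p) * int (f''(u))^2 du

with unit weights.  p = 1 gives the natural cubic interpolant, p = 0 the
ordinary least-squares straight line.  Because the objective is equivalent to
``sum (y-f)^2 + lam * int (f'')^2`` with lam = (1-p)/p, the solve is delegated
to :func:`scipy.interpolate.make_smoothing_spline` for five or more points;
for 3-4 points the Reinsch closed form is used (the minimizer is the natural
cubic interpolant through the ridge-regularized fitted values).

No rescaling of p by knot spacing or data magnitude is performed: the same
p applied to differently scaled ordinates smooths by a different amount,
exactly as in the MATLAB convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, make_interp_spline, make_smoothing_spline

__all__ = ["SplineFit", "fit_smoothing_spline", "roughness_matrix"]


def roughness_matrix(t: np.ndarray) -> np.ndarray:
    """Green-Silverman penalty matrix K with a'Ka = int f''(u)^2 du.

    Valid for the natural cubic spline f interpolating values ``a`` at the
    strictly increasing knots ``t``; K = Q R^{-1} Q' with the standard
    second-difference (Q) and overlap (R) band matrices.
    """
    t = np.asarray(t, dtype=float)
    n = t.size
    if n < 3:
        raise ValueError("need at least 3 knots")
    h = np.diff(t)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        Q[j - 1, j - 1] = 1.0 / h[j - 1]
        Q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, j - 1] = 1.0 / h[j]
        R[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < n - 2:
            R[j - 1, j] = R[j, j - 1] = h[j] / 6.0
    return Q @ np.linalg.solve(R, Q.T)


@dataclass
class SplineFit:
    """A fitted penalized spline, evaluable with its first derivative."""

    knots: np.ndarray
    p: float
    fitted_variable: str
    _spline: object  # scipy BSpline / CubicSpline / PPoly-compatible

    def __call__(self, t) -> np.ndarray:
        return np.asarray(self._spline(t))

    def derivative(self, t, nu: int = 1) -> np.ndarray:
        return np.asarray(self._spline.derivative(nu)(t))

    def residuals(self, y) -> np.ndarray:
        return np.asarray(y, dtype=float) - self(self.knots)


def fit_smoothing_spline(t, y, p: float,
                         fitted_variable: str = "") -> SplineFit:
    """Fit the csaps-objective smoothing spline to (t, y) at parameter p."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("t and y must be 1-D arrays of equal length")
    if t.size < 3:
        raise ValueError("smoothing spline needs at least 3 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing (duplicate or unsorted times)")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")

    if p == 0.0:
        # least-squares straight line, represented as a degree-1 spline
        slope, intercept = np.polyfit(t, y, 1)
        line = make_interp_spline(t[[0, -1]], slope * t[[0, -1]] + intercept, k=1)
        return SplineFit(knots=t, p=p, fitted_variable=fitted_variable, _spline=line)

    if p == 1.0:
        spline = CubicSpline(t, y, bc_type="natural")
    elif t.size >= 5:
        spline = make_smoothing_spline(t, y, lam=(1.0 - p) / p)
    else:
        # Reinsch closed form: fitted values from the regularized normal
        # equations, then the natural interpolant through them.
        K = roughness_matrix(t)
        a = np.linalg.solve(p * np.eye(t.size) + (1.0 - p) * K, p * y)
        spline = CubicSpline(t, a, bc_type="natural")
    return SplineFit(knots=t, p=p, fitted_variable=fitted_variable, _spline=spline)
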