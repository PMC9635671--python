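"""Locally estimated scatterplot smoothing (LOESS).

Tricube-weighted local polynomial regression, evaluable at arbitrary query
points, with optional bisquare robustness iterations.  Implemented in-house
because the trajectory analysis needs (a) evaluation at milestone
generations that are not data points, (b) a configurable polynomial degree,
and (c) robustness weighting combined with off-grid evaluation; a test
cross-checks the degree-1 path against an independent library
implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w ** 3


def _bisquare(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - u ** 2, 0.0, None)
    return w ** 2


def _local_fit(x: np.ndarray, y: np.ndarray, x0: float, q: int, degree: int,
               robust_w: np.ndarray) -> float:
    """Weighted polynomial fit around x0, evaluated at x0."""
    d = np.abs(x - x0)
    # distance to the q-th nearest point defines the bandwidth
    idx = np.argsort(d, kind="stable")[:q]
    h = d[idx].max()
    if h == 0:
        # all selected points coincide with x0
        w = robust_w[idx]
        return float(np.average(y[idx], weights=w) if w.sum() > 0
                     else y[idx].mean())
    w = _tricube(d[idx] / h) * robust_w[idx]
    if w.sum() <= 0:
        w = _tricube(d[idx] / h)
    xs, ys = x[idx], y[idx]
    # centred design for conditioning; evaluate at 0
    dx = xs - x0
    X = np.vander(dx, degree + 1, increasing=True)
    W = w[:, None]
    A = X.T @ (W * X)
    b = X.T @ (w * ys)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(beta[0])


@dataclass
class LoessFit:
    """A fitted LOESS curve, callable at any point within its support."""

    x: np.ndarray
    y: np.ndarray
    span: float
    degree: int
    robustness_iterations: int
    robust_weights: np.ndarray

    @property
    def support(self) -> tuple[float, float]:
        return float(self.x.min()), float(self.x.max())

    def __call__(self, x_new):
        """Evaluate the fit; queries outside the data range are clamped.

        Below the first (above the last) observation the curve extends as a
        constant -- local polynomials are not trusted to extrapolate, so
        e.g. evaluating at generation 0 when the first usable cycle ends at
        generation ~6 returns the boundary value rather than an
        extrapolation.
        """
        scalar = np.isscalar(x_new)
        xq = np.atleast_1d(np.asarray(x_new, dtype=float))
        xq = np.clip(xq, self.x.min(), self.x.max())
        q = max(self.degree + 1, int(math.ceil(self.span * len(self.x))))
        q = min(q, len(self.x))
        out = np.array([_local_fit(self.x, self.y, x0, q, self.degree,
                                   self.robust_weights) for x0 in xq])
        return float(out[0]) if scalar else out


def loess_fit(x: np.ndarray, y: np.ndarray, span: float = 0.75,
              degree: int = 1, robustness_iterations: int = 2) -> LoessFit:
    """Fit a LOESS curve of y on x.

    Parameters
    ----------
    x, y : arrays of equal length
        Data; x need not be sorted but must contain at least ``degree + 2``
        distinct values.
    span : fraction in (0, 1]
        Fraction of points entering each local fit (tricube-weighted by
        distance to the query point, bandwidth set by the furthest included
        point).
    degree : 0, 1 or 2
        Local polynomial degree.  Degree 1 reproduces straight-line data
        exactly.
    robustness_iterations
        Number of bisquare reweighting passes downweighting outliers; 0
        gives plain LOESS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < degree + 2:
        raise ParameterError(f"need at least {degree + 2} points, got {n}")
    q = max(degree + 1, int(math.ceil(span * n)))
    if q > n:
        raise ParameterError(f"span {span} selects {q} points but only {n} exist")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    robust_w = np.ones(n)
    for _ in range(robustness_iterations):
        fit = LoessFit(xs, ys, span, degree, 0, robust_w)
        resid = ys - fit(xs)
        s = np.median(np.abs(resid))
        if s <= 1e-12 * max(1.0, float(np.median(np.abs(ys)))):
            break  # (near-)interpolating fit; weights stay uniform
        robust_w = _bisquare(resid / (6.0 * s))
    return LoessFit(xs, ys, span, degree, robustness_iterations, robust_w)
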