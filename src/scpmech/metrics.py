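"""Goodness-of-fit and curve-comparison statistics.

Implements the coefficient of determination, root-mean-square error, a
two-component (size/shape) curve-correlation rating with equal weights, and
Richardson extrapolation of mesh-refinement scalar triplets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import Trajectory
from .errors import InputError

__all__ = [
    "CORAResult",
    "RichardsonResult",
    "r_squared",
    "rmse",
    "cora_rating",
    "richardson_extrapolate",
]


@dataclass(frozen=True)
class CORAResult:
    """Two-component curve-correlation rating with equal 0.5/0.5 weights."""

    size_rating: float
    shape_rating: float
    total: float
    weights: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self):
        for v in (self.size_rating, self.shape_rating, self.total):
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise InputError(f"rating components must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class RichardsonResult:
    """Observed convergence order and zero-mesh-size extrapolation."""

    observed_order: float
    extrapolated_value: float
    percent_differences: tuple[float, ...]
    asymptotic: bool
    oscillatory: bool = False
    degenerate: bool = False


def _check_pair(observed, predicted, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.ndim != 1 or pred.ndim != 1 or obs.shape != pred.shape:
        raise InputError("observed and predicted must be 1-D arrays of equal length")
    if obs.size < min_len:
        raise InputError(f"need at least {min_len} samples")
    return obs, pred


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``R^2 = 1 - RSS/TSS``.

    At most 1; may be negative for fits worse than the mean.  Undefined for a
    constant observed vector.
    """
    obs, pred = _check_pair(observed, predicted, 2)
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        raise InputError("R^2 is undefined for a constant observed vector")
    rss = float(np.sum((obs - pred) ** 2))
    return 1.0 - rss / tss


def rmse(observed, predicted) -> float:
    """Root-mean-square error between two equal-length vectors."""
    obs, pred = _check_pair(observed, predicted, 1)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def _as_signal(obj) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, Trajectory):
        return obj.times, obj.displacements
    if hasattr(obj, "strain") and hasattr(obj, "stress"):
        return obj.strain, obj.stress
    x, y = obj
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def cora_rating(reference, candidate, shift_fraction: float = 0.1,
                grid_points: int = 512) -> CORAResult:
    """Size/shape curve-correlation rating on the common abscissa window.

    size  = min(A_ref, A_cand) / max(A_ref, A_cand), A = integral of |y|;
    shape = maximum normalized cross-correlation of the two derivative
    signals over shifts within ``shift_fraction`` of the window, clamped to
    [0, 1]; total = equal-weighted mean.
    """
    x_r, y_r = _as_signal(reference)
    x_c, y_c = _as_signal(candidate)
    lo, hi = max(x_r[0], x_c[0]), min(x_r[-1], x_c[-1])
    if hi <= lo:
        raise InputError("signals have no overlapping support")
    grid = np.linspace(lo, hi, grid_points)
    f_r = np.interp(grid, x_r, y_r)
    f_c = np.interp(grid, x_c, y_c)

    a_r = float(np.trapezoid(np.abs(f_r), grid))
    a_c = float(np.trapezoid(np.abs(f_c), grid))
    if a_r == 0.0 and a_c == 0.0:
        size = 1.0
    elif a_r == 0.0 or a_c == 0.0:
        size = 0.0
    else:
        size = min(a_r, a_c) / max(a_r, a_c)

    d_r = np.gradient(f_r, grid)
    d_c = np.gradient(f_c, grid)
    max_shift = max(1, int(round(shift_fraction * grid_points)))
    best = -1.0
    for shift in range(-max_shift, max_shift + 1):
        if shift >= 0:
            a, b = d_r[shift:], d_c[: grid_points - shift]
        else:
            a, b = d_r[:shift], d_c[-shift:]
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        if denom == 0.0:
            corr = 1.0 if np.allclose(a, b) else 0.0
        else:
            corr = float(np.dot(a, b) / denom)
        best = max(best, corr)
    shape = min(max(best, 0.0), 1.0)

    total = 0.5 * size + 0.5 * shape
    return CORAResult(size_rating=size, shape_rating=shape, total=total)


def richardson_extrapolate(mesh_sizes, values) -> RichardsonResult:
    """Observed-order Richardson extrapolation from three mesh solutions.

    Requires ``h1 > h2 > h3`` with a constant refinement ratio (within 1%).
    ``p = ln|(f1 - f2)/(f2 - f3)| / ln r`` and the zero-size estimate is
    ``f3 + (f3 - f2)/(r^p - 1)``.  Oscillatory convergence (sign change in
    successive differences) is flagged and the extrapolation withheld.
    """
    h = np.asarray(mesh_sizes, dtype=float)
    f = np.asarray(values, dtype=float)
    if h.shape != (3,) or f.shape != (3,):
        raise InputError("exactly three mesh sizes and three values required")
    if not (h[0] > h[1] > h[2] > 0):
        raise InputError("mesh sizes must be strictly decreasing and positive")
    r1, r2 = h[0] / h[1], h[1] / h[2]
    if abs(r1 - r2) > 0.01 * r2:
        raise InputError("refinement ratio must be constant within 1%")
    r = 0.5 * (r1 + r2)

    pct = []
    for i in range(2):
        diff = abs(f[i] - f[i + 1])
        denom = abs(f[i + 1])
        pct.append(0.0 if diff == 0.0 else
                   (math.inf if denom == 0.0 else float(diff / denom * 100.0)))
    pct = tuple(pct)

    d1, d2 = f[0] - f[1], f[1] - f[2]
    if d1 == 0.0 and d2 == 0.0:
        return RichardsonResult(
            observed_order=math.nan, extrapolated_value=float(f[2]),
            percent_differences=pct, asymptotic=False, degenerate=True,
        )
    if d2 == 0.0 or d1 * d2 < 0.0:
        return RichardsonResult(
            observed_order=math.nan, extrapolated_value=math.nan,
            percent_differences=pct, asymptotic=False, oscillatory=True,
        )

    p = math.log(abs(d1 / d2)) / math.log(r)
    if p <= 0:
        return RichardsonResult(
            observed_order=p, extrapolated_value=math.nan,
            percent_differences=pct, asymptotic=False,
        )
    extrapolated = float(f[2] + (f[2] - f[1]) / (r**p - 1.0))
    return RichardsonResult(
        observed_order=p, extrapolated_value=extrapolated,
        percent_differences=pct, asymptotic=True,
    )
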