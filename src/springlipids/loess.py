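"""Locally weighted polynomial regression (LOESS) with pointwise intervals.

A from-scratch local regression smoother: at each evaluation point the
nearest ``ceil(span * n)`` observations are fitted by weighted least
squares of degree 1 or 2 with tricube weights on scaled distance, and the
fitted value is the local polynomial at that point. Because every fitted
value is a linear functional l(x)'y of the responses, pointwise standard
errors follow from ||l(x)||² times a residual variance whose degrees of
freedom use the standard smoother-matrix trace correction
(n − 2·tr L + tr L'L). Confidence intervals are t-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class LoessFit:
    """LOESS evaluated on a grid, with 95% pointwise confidence bounds."""

    grid: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    span: float
    degree: int
    df_residual: float
    sigma2: float


def _local_weights(
    x: np.ndarray, x0: float, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the k nearest points to x0 and their tricube weights."""
    d = np.abs(x - x0)
    idx = np.argpartition(d, k - 1)[:k]
    dmax = d[idx].max()
    if dmax == 0:
        w = np.ones(k)
    else:
        u = np.clip(d[idx] / dmax, 0.0, 1.0)
        w = (1.0 - u**3) ** 3
    return idx, w


def _hat_row(
    x: np.ndarray, y: np.ndarray, x0: float, k: int, degree: int
) -> tuple[float, np.ndarray]:
    """Fitted value at x0 and the equivalent-kernel row l(x0) over all n."""
    idx, w = _local_weights(x, x0, k)
    # centre at x0 so the intercept of the local polynomial is the fit
    xc = x[idx] - x0
    A = np.vander(xc, degree + 1, increasing=True)
    sw = np.sqrt(w)
    Aw = A * sw[:, None]
    # l(x0) = e1' (A'WA)^+ A'W  restricted to the window
    AtWA = Aw.T @ Aw
    try:
        first_row = np.linalg.solve(AtWA, np.eye(degree + 1)[:, 0])
    except np.linalg.LinAlgError:
        first_row = np.linalg.pinv(AtWA)[0]
    l_local = (A * w[:, None]) @ first_row
    row = np.zeros(x.size)
    row[idx] = l_local
    return float(row @ y), row


def loess(
    x,
    y,
    grid,
    span: float = 0.75,
    degree: int = 2,
    ci_level: float = 0.95,
    compute_ci: bool = True,
) -> LoessFit:
    """Fit a LOESS curve on an evaluation grid.

    Parameters
    ----------
    span
        Fraction of the data in each local window, in (0, 1].
    degree
        Local polynomial degree, 1 or 2.
    compute_ci
        Skip the O(n²) smoother-matrix pass (intervals become NaN) when
        only the curve or its argmax is needed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if np.ptp(x) == 0:
        raise ValueError("all x values are equal")
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)

    fitted = np.empty(grid.size)
    rows = np.empty((grid.size, n)) if compute_ci else None
    for j, x0 in enumerate(grid):
        f, row = _hat_row(x, y, x0, k, degree)
        fitted[j] = f
        if compute_ci:
            rows[j] = row

    if not compute_ci:
        nanv = np.full(grid.size, np.nan)
        return LoessFit(grid, fitted, nanv, nanv.copy(), span, degree,
                        np.nan, np.nan)

    # smoother matrix at the data points, for sigma^2 and residual df
    L = np.empty((n, n))
    yhat = np.empty(n)
    for i, xi in enumerate(x):
        yhat[i], L[i] = _hat_row(x, y, xi, k, degree)
    resid = y - yhat
    tr_l = np.trace(L)
    tr_ltl = float((L * L).sum())
    df = max(n - 2.0 * tr_l + tr_ltl, 1.0)
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * (rows**2).sum(axis=1))
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df)
    return LoessFit(
        grid=grid,
        fitted=fitted,
        ci_low=fitted - tcrit * se,
        ci_high=fitted + tcrit * se,
        span=span,
        degree=degree,
        df_residual=df,
        sigma2=sigma2,
    )
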