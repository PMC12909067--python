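"""Spearman and simple-linear-regression screens of lipid responses.

Spring geochemistry is rarely normally distributed, so the first-pass
association screen is nonparametric (Spearman's rho on mid-ranks). Simple
linear regressions on standardized predictors complement it with slopes and
(adjusted) R². Missing values are removed pairwise per test and the usable
n is always reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class ScreenResult:
    """One (response, predictor) association test."""

    response_name: str
    predictor_name: str
    method: str  # "spearman" | "slr"
    rho: Optional[float]
    p_value: Optional[float]
    n_used: int
    valid: bool = True
    note: str = ""
    slope: Optional[float] = None
    intercept: Optional[float] = None
    r2: Optional[float] = None
    adjusted_r2: Optional[float] = None


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t",
) -> tuple[float, float]:
    """Spearman's rho on mid-ranks with its p-value.

    ``method='t'`` uses the t-approximation with n−2 degrees of freedom
    (scipy's default, appropriate for the sample sizes seen here);
    ``method='exact'`` enumerates all rank permutations (n ≤ 9 only).

    Raises on fewer than 3 complete pairs, and on a constant vector, where
    rho is undefined — the caller sees an explicit error rather than a
    silent NaN.
    """
    xs, ys = _pairwise_complete(x, y)
    n = xs.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("constant vector: Spearman's rho is undefined")
    rho, p = stats.spearmanr(xs, ys)
    rho = float(rho)
    if method == "exact":
        if n > 9:
            raise ValueError("exact permutation p only supported for n <= 9")
        rx = stats.rankdata(xs)
        ry = stats.rankdata(ys)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
    elif method != "t":
        raise ValueError(f"unknown method {method!r}")
    return rho, float(p)


def slr(
    response: Sequence[float],
    predictor: Sequence[float],
    standardize: bool = True,
) -> ScreenResult:
    """Simple OLS of a response on one (standardized) predictor.

    The predictor is centred and scaled to unit SD before the fit so slopes
    are comparable across analytes of very different magnitudes; R² and the
    slope t-test p are invariant to that scaling.
    """
    y, x = _pairwise_complete(response, predictor)
    n = y.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return ScreenResult(
        response_name="y",
        predictor_name="x",
        method="slr",
        rho=None,
        p_value=float(fit.pvalues[1]),
        n_used=n,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        adjusted_r2=float(fit.rsquared_adj),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (non-default companion column)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def screen_all(
    samples: pd.DataFrame,
    responses: Iterable[str],
    predictors: Iterable[str],
    methods: Iterable[str] = ("spearman", "slr"),
    alpha: float = 0.05,
    add_bh: bool = False,
) -> pd.DataFrame:
    """Run every (response, predictor, method) test on a sample table.

    One row per combination (and per lipid fraction if a ``fraction_label``
    column is present); constant inputs yield a flagged invalid row rather
    than an error, so a heterogeneous compilation never aborts the screen.
    Significance is flagged at raw p < ``alpha``; ``add_bh`` appends a
    Benjamini-Hochberg column per method.
    """
    responses = list(responses)
    predictors = list(predictors)
    methods = list(methods)
    if not responses or not predictors:
        raise ValueError("need at least one response and one predictor")

    if "fraction_label" in samples.columns:
        groups = list(samples.groupby("fraction_label"))
    else:
        groups = [("", samples)]

    rows = []
    for label, sub in groups:
        for resp, pred, method in itertools.product(
            responses, predictors, methods
        ):
            row = {
                "fraction_label": label,
                "response": resp,
                "predictor": pred,
                "method": method,
            }
            try:
                if method == "spearman":
                    rho, p = spearman(sub[pred], sub[resp])
                    xs, ys = _pairwise_complete(sub[pred], sub[resp])
                    row.update(
                        rho=rho, p_value=p, n_used=xs.size, valid=True
                    )
                elif method == "slr":
                    res = slr(sub[resp], sub[pred])
                    row.update(
                        rho=None,
                        p_value=res.p_value,
                        n_used=res.n_used,
                        slope=res.slope,
                        intercept=res.intercept,
                        r2=res.r2,
                        adjusted_r2=res.adjusted_r2,
                        valid=True,
                    )
                else:
                    raise ValueError(f"unknown method {method!r}")
            except ValueError as err:
                row.update(
                    rho=None, p_value=None, n_used=0, valid=False,
                    note=str(err),
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    out["p_value"] = out["p_value"].astype(float)
    out["significant"] = out["p_value"] < alpha
    if add_bh:
        out["p_bh"] = np.nan
        for method in methods:
            mask = (out["method"] == method) & out["valid"]
            if mask.any():
                out.loc[mask, "p_bh"] = bh_adjust(out.loc[mask, "p_value"])
    return out
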