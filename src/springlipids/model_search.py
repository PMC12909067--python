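"""Exhaustive all-subsets multiple linear regression ranked by adjusted R².

With k candidate geochemical predictors there are 2^k − 1 non-empty
subsets (127 for the seven-analyte panel: pH, temperature, DO, SPC, ORP,
Fe(II), sulphide). Every subset is fitted by OLS on standardized
predictors and ranked by adjusted R²; the "top models" view keeps the
best ten among those whose overall F-test clears p < 0.05 and tallies how
often each predictor appears in them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class ModelResult:
    """One fitted OLS model over a predictor subset."""

    predictor_subset: tuple[str, ...]
    coefficients: dict[str, float]  # on standardized predictors
    intercept: float
    model_p_value: float
    r2: float
    adjusted_r2: float
    n: int
    rank_by_adj_r2: int = 0


@dataclass
class SearchReport:
    """All-subsets search output: every model, ranked, plus skipped subsets."""

    models: list[ModelResult]
    skipped: list[tuple[tuple[str, ...], str]] = field(default_factory=list)
    alpha: float = 0.05
    top_m: int = 10

    def top_significant(self) -> list[ModelResult]:
        """The best ``top_m`` models by adjusted R² with F-test p < alpha."""
        sig = [m for m in self.models if m.model_p_value < self.alpha]
        return sig[: self.top_m]

    def inclusion_counts(self) -> dict[str, int]:
        """How many of the top significant models contain each predictor."""
        top = self.top_significant()
        counts: dict[str, int] = {}
        for m in top:
            for p in m.predictor_subset:
                counts[p] = counts.get(p, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            rows.append(
                {
                    "rank": m.rank_by_adj_r2,
                    "predictors": "+".join(m.predictor_subset),
                    "k": len(m.predictor_subset),
                    "n": m.n,
                    "r2": m.r2,
                    "adjusted_r2": m.adjusted_r2,
                    "model_p_value": m.model_p_value,
                }
            )
        return pd.DataFrame(rows)


def enumerate_subsets(predictors: Sequence[str]) -> list[tuple[str, ...]]:
    """All 2^k − 1 non-empty predictor subsets, by size then lexicographic."""
    names = list(predictors)
    if len(set(names)) != len(names):
        raise ValueError("duplicate predictor names")
    if not 1 <= len(names) <= 20:
        raise ValueError("predictor count must be in [1, 20]")
    ordered = sorted(names)
    subsets: list[tuple[str, ...]] = []
    for size in range(1, len(ordered) + 1):
        subsets.extend(itertools.combinations(ordered, size))
    return subsets


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance predictors: {zero}")
    return (X - X.mean()) / sd


def fit_mlr(
    response: Sequence[float],
    predictor_matrix: pd.DataFrame,
    standardize: bool = True,
) -> ModelResult:
    """OLS with intercept on (standardized) predictors.

    Reports R², adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) and the
    overall F-test p. Requires n > p + 1 complete cases and a full-rank
    design; a rank-deficient design raises an error naming the collinear
    columns.
    """
    y = np.asarray(response, dtype=float)
    X = predictor_matrix.astype(float)
    keep = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    y, X = y[keep], X.loc[keep]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n = {n} <= p + 1 = {p + 1}: model unidentifiable")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    if standardize:
        X = _standardize(X)
    design = np.column_stack([np.ones(n), X.to_numpy()])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # identify the offending columns by incremental rank growth
        bad = []
        cols = [np.ones(n)]
        for name in X.columns:
            trial = np.column_stack(cols + [X[name].to_numpy()])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(name)
            else:
                cols.append(X[name].to_numpy())
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    return ModelResult(
        predictor_subset=tuple(X.columns),
        coefficients=dict(zip(X.columns, map(float, fit.params[1:]))),
        intercept=float(fit.params[0]),
        model_p_value=float(fit.f_pvalue),
        r2=float(fit.rsquared),
        adjusted_r2=float(fit.rsquared_adj),
        n=n,
    )


def fit_mlr_extended(
    response: Sequence[float],
    predictor_matrix: pd.DataFrame,
    include_quadratics: bool = False,
    include_interactions: bool = False,
    standardize: bool = True,
) -> ModelResult:
    """As :func:`fit_mlr` after adding squared and/or pairwise product terms.

    Terms are built from standardized predictors, then the expanded design
    is fitted unstandardized (re-scaling squares would destroy their shape).
    With both flags off this is exactly :func:`fit_mlr`.
    """
    if not (include_quadratics or include_interactions):
        return fit_mlr(response, predictor_matrix, standardize=standardize)
    X = predictor_matrix.astype(float)
    Xs = _standardize(X) if standardize else X
    cols = {c: Xs[c] for c in Xs.columns}
    if include_quadratics:
        for c in Xs.columns:
            cols[f"{c}^2"] = Xs[c] ** 2
    if include_interactions:
        for a, b in itertools.combinations(Xs.columns, 2):
            cols[f"{a}:{b}"] = Xs[a] * Xs[b]
    expanded = pd.DataFrame(cols, index=Xs.index)
    return fit_mlr(response, expanded, standardize=False)


def search(
    samples: pd.DataFrame,
    response: str,
    predictors: Iterable[str],
    alpha: float = 0.05,
    top_m: int = 10,
    listwise: bool = False,
) -> SearchReport:
    """Fit every non-empty predictor subset and rank by adjusted R².

    Complete cases are taken per subset (over that subset's predictors) by
    default, so each model uses the maximum usable n; ``listwise`` restricts
    every model to rows complete across all candidate predictors for strict
    comparability. Subsets that cannot be fitted (too few cases, collinear)
    are recorded as skipped rather than silently dropped. Exact adjusted-R²
    ties rank the smaller subset first, then lexicographic names.
    """
    predictors = list(predictors)
    yvals = samples[response].dropna().to_numpy(dtype=float)
    if yvals.size == 0 or np.ptp(yvals) == 0:
        raise ValueError(f"response {response!r} is constant or empty")
    base = samples
    if listwise:
        base = samples.dropna(subset=[response, *predictors])
    models: list[ModelResult] = []
    skipped: list[tuple[tuple[str, ...], str]] = []
    for subset in enumerate_subsets(predictors):
        try:
            models.append(
                fit_mlr(base[response], base.loc[:, list(subset)])
            )
        except ValueError as err:
            skipped.append((subset, str(err)))
    models.sort(
        key=lambda m: (
            -m.adjusted_r2,
            len(m.predictor_subset),
            m.predictor_subset,
        )
    )
    for i, m in enumerate(models, start=1):
        m.rank_by_adj_r2 = i
    return SearchReport(models=models, skipped=skipped, alpha=alpha,
                        top_m=top_m)
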