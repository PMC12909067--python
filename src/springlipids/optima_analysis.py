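"""Binned summaries and LOESS optimum estimation for crenarchaeol abundance.

Crenarchaeol relative abundance peaks at circumneutral pH and moderate
temperature. Two complementary views quantify that: box-style summaries in
half-open bins (0.5 pH units / 5 °C, edges at multiples of the width,
labelled by their minimum bound), and a LOESS curve whose grid argmax with
a 95% pointwise envelope estimates the optimum and its uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geochemistry import classify_acidity
from .lipid_indices import detectability_stats
from .loess import loess

#: conventional bin widths per variable
DEFAULT_BIN_WIDTH = {"ph": 0.5, "temperature": 5.0}
#: conventional evaluation-grid steps per variable
DEFAULT_GRID_STEP = {"ph": 0.01, "temperature": 0.1}


@dataclass
class OptimumEstimate:
    """A LOESS response curve and the location/value of its maximum."""

    grid: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    x_opt: float
    y_opt: float
    boundary_flag: bool
    span: float
    degree: int


def bin_summaries(
    samples: pd.DataFrame,
    variable: str,
    bin_width: float | None = None,
    response: str = "cren_fraction",
) -> pd.DataFrame:
    """Per-bin n, mean, median, quartiles and extremes of the response.

    Bins are half-open ``[m, m + width)`` with edges at multiples of the
    width; empty bins are omitted. Quartiles use linear interpolation
    between order statistics (type-7), so box statistics reproduce exactly.
    """
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTH.get(variable, 1.0)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sub = samples.dropna(subset=[variable, response])
    if sub.empty:
        warnings.warn("no samples with both variable and response",
                      stacklevel=2)
        return pd.DataFrame(
            columns=["bin_min", "bin_width", "n", "mean", "median",
                     "q1", "q3", "min", "max"]
        )
    x = sub[variable].to_numpy(dtype=float)
    v = sub[response].to_numpy(dtype=float)
    bin_idx = np.floor(x / bin_width + 1e-12).astype(int)
    rows = []
    for b in sorted(set(bin_idx)):
        vals = v[bin_idx == b]
        rows.append(
            {
                "bin_min": b * bin_width,
                "bin_width": bin_width,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "median": float(np.quantile(vals, 0.5)),
                "q1": float(np.quantile(vals, 0.25)),
                "q3": float(np.quantile(vals, 0.75)),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows)


def loess_optimum(
    x,
    y,
    span: float = 0.75,
    degree: int = 2,
    grid_step: float = 0.01,
    compute_ci: bool = True,
) -> OptimumEstimate:
    """LOESS curve of y over x and the grid location of its maximum.

    Requires n ≥ 20. The curve is evaluated on a regular grid from min(x)
    to max(x) with the given step; ``boundary_flag`` marks an argmax at a
    grid endpoint, where a true interior optimum cannot be claimed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 20:
        raise ValueError(f"need at least 20 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("all x values are equal")
    grid = np.arange(x.min(), x.max() + grid_step / 2.0, grid_step)
    fit = loess(x, y, grid, span=span, degree=degree, compute_ci=compute_ci)
    i_opt = int(np.argmax(fit.fitted))
    return OptimumEstimate(
        grid=fit.grid,
        fitted=fit.fitted,
        ci_low=fit.ci_low,
        ci_high=fit.ci_high,
        x_opt=float(grid[i_opt]),
        y_opt=float(fit.fitted[i_opt]),
        boundary_flag=i_opt in (0, grid.size - 1),
        span=span,
        degree=degree,
    )


def class_means(
    samples: pd.DataFrame,
    split: str = "acidity",
    response: str = "cren_fraction",
    detect_threshold: float = 0.0,
) -> dict[str, dict]:
    """Detectability and mean response per class of a two-way split.

    ``acidity``: acidic (pH < 7) vs alkaline (pH ≥ 7);
    ``temperature_60``: hot (≥ 60 °C) vs cool (< 60 °C).
    Empty classes are reported with n_total = 0 and undefined means.
    """
    if split == "acidity":
        labels = samples["ph"].map(
            lambda p: classify_acidity(p, mode="fixed7")
        )
        classes = ("acidic", "alkaline")
    elif split == "temperature_60":
        labels = np.where(samples["temperature"] >= 60.0, "hot", "cool")
        labels = pd.Series(labels, index=samples.index)
        classes = ("hot", "cool")
    else:
        raise ValueError(f"unknown split {split!r}")
    out = {}
    for cls in classes:
        vals = samples.loc[labels == cls, response]
        out[cls] = detectability_stats(vals, detect_threshold)
    return out
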