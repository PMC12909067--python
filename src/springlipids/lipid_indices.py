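"""Ring Index and crenarchaeol abundance metrics for iGDGT lipid profiles.

Isoprenoid GDGTs (iGDGT-0 … iGDGT-8, here ``G0`` … ``G8``) carry 0-8
cyclopentyl rings; crenarchaeol (``Cren``) and its isomer (``CrenIso``)
additionally carry a cyclohexyl ring but contribute four cyclopentyl rings.
The Ring Index (RI) is the abundance-weighted mean cyclopentyl ring count of
a profile, computed either with crenarchaeol included as a four-ringed
member or restricted to the G0-G8 series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

#: canonical species order of an iGDGT profile
SPECIES: tuple[str, ...] = (
    "G0", "G1", "G2", "G3", "G4", "G5", "G6", "G7", "G8", "Cren", "CrenIso",
)

#: cyclopentyl ring count per species; crenarchaeol and its isomer count as
#: four-ringed members (the cyclohexyl ring is not counted)
RING_WEIGHTS: dict[str, float] = {
    **{f"G{n}": float(n) for n in range(9)},
    "Cren": 4.0,
    "CrenIso": 4.0,
}

_G_SPECIES = tuple(f"G{n}" for n in range(9))


class EmptyProfileError(ValueError):
    """Raised when a lipid profile has no positive abundance to normalize."""


@dataclass(frozen=True)
class LipidProfile:
    """Normalized relative abundances of the iGDGT species of one sample.

    Abundances are non-negative and sum to 1; species absent from the
    source table are stored as 0.
    """

    abundances: Mapping[str, float]
    fraction_label: str = "CL"

    def __post_init__(self) -> None:
        extra = set(self.abundances) - set(SPECIES)
        if extra:
            raise ValueError(f"unknown lipid species: {sorted(extra)}")
        vals = np.array([self.abundances.get(s, 0.0) for s in SPECIES])
        if (vals < 0).any():
            raise ValueError("abundances must be non-negative")
        object.__setattr__(
            self,
            "abundances",
            dict(zip(SPECIES, vals)),
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.abundances[s] for s in SPECIES])

    @property
    def total(self) -> float:
        return float(self.as_array().sum())


def normalize_abundances(
    areas: Mapping[str, float], fraction_label: str = "CL"
) -> LipidProfile:
    """Turn raw peak areas into a profile of relative abundances summing to 1.

    Parameters
    ----------
    areas
        Peak area (or any non-negative abundance measure) per species.
        Missing species are treated as 0.

    Raises
    ------
    EmptyProfileError
        If all areas are zero.
    ValueError
        If any area is negative or a species name is unknown.
    """
    extra = set(areas) - set(SPECIES)
    if extra:
        raise ValueError(f"unknown lipid species: {sorted(extra)}")
    vals = np.array([float(areas.get(s, 0.0)) for s in SPECIES])
    if (vals < 0).any():
        bad = [s for s, v in zip(SPECIES, vals) if v < 0]
        raise ValueError(f"negative area for {bad}")
    total = vals.sum()
    if total <= 0:
        raise EmptyProfileError("all peak areas are zero; empty profile")
    return LipidProfile(dict(zip(SPECIES, vals / total)), fraction_label)


def _coerce(profile: LipidProfile | Mapping[str, float]) -> np.ndarray:
    if isinstance(profile, LipidProfile):
        return profile.as_array()
    return np.array([float(profile.get(s, 0.0)) for s in SPECIES])


def ring_index(
    profile: LipidProfile | Mapping[str, float],
    include_cren: bool = True,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Abundance-weighted mean cyclopentyl ring count of a profile.

    With ``include_cren`` the average runs over all species with
    crenarchaeol and its isomer weighted as four-ringed members; without it
    the average runs over the G0-G8 series only (crenarchaeol excluded from
    numerator and denominator). The operation normalizes internally, so any
    uniform rescaling of the input leaves the result unchanged.
    """
    w = dict(RING_WEIGHTS if weights is None else weights)
    vals = _coerce(profile)
    if (vals < 0).any():
        raise ValueError("abundances must be non-negative")
    if include_cren:
        keep = np.ones(len(SPECIES), dtype=bool)
    else:
        keep = np.array([s in _G_SPECIES for s in SPECIES])
    denom = vals[keep].sum()
    if denom <= 0:
        raise EmptyProfileError(
            "no abundance in the relevant species set (empty denominator)"
        )
    wvec = np.array([w[s] for s in SPECIES])
    return float((vals[keep] * wvec[keep]).sum() / denom)


def cren_fraction(
    profile: LipidProfile | Mapping[str, float],
    include_isomer: bool = False,
) -> float:
    """Crenarchaeol relative abundance: Cren over the total of all species.

    By default the isomer (Cren') is counted in the denominator only;
    ``include_isomer`` adds it to the numerator.
    """
    vals = _coerce(profile)
    if (vals < 0).any():
        raise ValueError("abundances must be non-negative")
    total = vals.sum()
    if total <= 0:
        raise EmptyProfileError("empty profile")
    num = vals[SPECIES.index("Cren")]
    if include_isomer:
        num += vals[SPECIES.index("CrenIso")]
    return float(num / total)


def detectability_stats(
    cren_fractions: Iterable[float],
    detect_threshold: float = 0.0,
) -> dict:
    """Detect / non-detect counts and mean crenarchaeol fraction of a group.

    A sample is a non-detect when its crenarchaeol relative abundance is at
    or below ``detect_threshold`` (default: exactly 0, i.e., absent from the
    reported table). An empty group yields ``n_total = 0`` with the means
    flagged undefined (``None``), never silently zero.
    """
    f = np.asarray(list(cren_fractions), dtype=float)
    n_total = int(f.size)
    if n_total == 0:
        return {
            "n_total": 0,
            "n_detect": 0,
            "n_nondetect": 0,
            "fraction_detect": None,
            "mean_fraction": None,
            "mean_fraction_excluding_zeros": None,
        }
    detected = f > detect_threshold
    n_detect = int(detected.sum())
    return {
        "n_total": n_total,
        "n_detect": n_detect,
        "n_nondetect": n_total - n_detect,
        "fraction_detect": n_detect / n_total,
        "mean_fraction": float(f.mean()),
        "mean_fraction_excluding_zeros": (
            float(f[detected].mean()) if n_detect else None
        ),
    }


def grouped_detectability(
    samples: pd.DataFrame,
    group_predicate: Callable[[pd.Series], object] | str,
    response: str = "cren_fraction",
    detect_threshold: float = 0.0,
) -> pd.DataFrame:
    """Apply :func:`detectability_stats` per group of a sample table.

    ``group_predicate`` is a column name or a per-row callable returning the
    group label.
    """
    if callable(group_predicate):
        labels = samples.apply(group_predicate, axis=1)
    else:
        labels = samples[group_predicate]
    rows = []
    for label, sub in samples.groupby(labels):
        stats = detectability_stats(sub[response], detect_threshold)
        rows.append({"group": label, **stats})
    return pd.DataFrame(rows)


def add_index_columns(
    table: pd.DataFrame,
    detect_threshold: float = 0.0,
    include_isomer: bool = False,
) -> pd.DataFrame:
    """Append ri_with_cren, ri_without_cren, cren_fraction and detect_flag.

    Rows whose G-series abundances are all zero get ``ri_without_cren`` as
    NaN (the denominator of the crenarchaeol-free variant is empty there).
    Species columns missing from the table are treated as zero with a
    warning, since compiled studies report heterogeneous species sets.
    """
    missing = [s for s in SPECIES if s not in table.columns]
    if missing:
        warnings.warn(
            f"species columns absent, treated as 0: {missing}", stacklevel=2
        )
    out = table.copy()
    ri_w, ri_wo, cf = [], [], []
    for _, row in table.iterrows():
        areas = {s: row[s] for s in SPECIES if s in table.columns}
        ri_w.append(ring_index(areas, include_cren=True))
        try:
            ri_wo.append(ring_index(areas, include_cren=False))
        except EmptyProfileError:
            ri_wo.append(np.nan)
        cf.append(cren_fraction(areas, include_isomer=include_isomer))
    out["ri_with_cren"] = ri_w
    out["ri_without_cren"] = ri_wo
    out["cren_fraction"] = cf
    out["detect_flag"] = out["cren_fraction"] > detect_threshold
    return out
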