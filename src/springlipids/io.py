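"""Sample-table IO and the end-to-end pipeline.

The sample CSV schema is one row per (sample, lipid fraction):

    site_id, source_study, fraction_label, temperature, ph, do_conc,
    spc, orp, fe2, sulfide, fe2_bd, sulfide_bd, G0..G8, Cren, CrenIso

Concentrations are mol/L unless a units manifest declares otherwise
(``{"fe2": "mg/L", "sulfide": "ug/L"}``); below-detection tokens
("B.D.", "<DL", "BD") are parsed into per-analyte flags and imputed
according to a configurable policy. ``run_pipeline`` chains indices →
correlation screen → all-subsets model search → binned summaries and
LOESS optima, writing one CSV per stage plus a JSON run manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .geochemistry import to_molar, impute_below_detection, MOLAR_MASS
from .lipid_indices import SPECIES, add_index_columns
from .correlation_screen import screen_all
from .model_search import search
from .optima_analysis import bin_summaries, loess_optimum, class_means

#: canonical column order of the sample CSV
SCHEMA_COLUMNS: tuple[str, ...] = (
    "site_id", "source_study", "fraction_label", "temperature", "ph",
    "do_conc", "spc", "orp", "fe2", "sulfide", "fe2_bd", "sulfide_bd",
    *SPECIES,
)

MANDATORY_COLUMNS: tuple[str, ...] = ("site_id", "temperature", "ph")

BD_TOKENS = {"B.D.", "BD", "b.d.", "bd", "<DL", "<dl", "B.D", "n.d.", "N.D."}

GEOCHEM_PREDICTORS: tuple[str, ...] = (
    "ph", "temperature", "do_conc", "spc", "orp", "fe2", "sulfide",
)


class SchemaError(ValueError):
    """Raised when a sample CSV fails validation; carries row-level detail."""

    def __init__(self, message: str, row_errors: Optional[list] = None):
        super().__init__(message)
        self.row_errors = row_errors or []


def read_samples(
    path,
    units: Optional[dict[str, str]] = None,
    bd_policy: str = "half_dl",
) -> pd.DataFrame:
    """Read and validate a sample CSV into the analysis table.

    ``units`` maps an analyte column (fe2, sulfide) to its on-disk unit;
    values are converted to mol/L. Below-detection tokens set
    ``<analyte>_bd`` and are imputed per ``bd_policy`` (half_dl | zero |
    exclude). Row-level numeric failures are collected and reported
    together with their line numbers.
    """
    units = units or {}
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [
        c for c in MANDATORY_COLUMNS if c not in raw.columns
    ] + [c for c in SPECIES if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")

    numeric_cols = [
        c for c in ("temperature", "ph", "do_conc", "spc", "orp",
                    "fe2", "sulfide", *SPECIES)
        if c in raw.columns
    ]
    out = pd.DataFrame(index=raw.index)
    for c in ("site_id", "source_study", "fraction_label"):
        out[c] = raw[c] if c in raw.columns else ""
    if "fraction_label" not in raw.columns:
        out["fraction_label"] = "CL"

    row_errors: list[str] = []
    bd_flags: dict[str, np.ndarray] = {}
    for c in numeric_cols:
        vals = np.full(len(raw), np.nan)
        bd = np.zeros(len(raw), dtype=bool)
        for i, token in enumerate(raw[c].str.strip()):
            if token == "" or token.upper() in {"NA", "NAN"}:
                continue
            if token in BD_TOKENS:
                bd[i] = True
                continue
            try:
                vals[i] = float(token)
            except ValueError:
                row_errors.append(
                    f"line {i + 2}: column {c!r}: cannot parse {token!r}"
                )
        out[c] = vals
        if c in MOLAR_MASS:
            bd_flags[c] = bd
        elif bd.any():
            out.loc[bd, c] = np.nan

    if row_errors:
        raise SchemaError(
            f"{len(row_errors)} malformed values:\n" + "\n".join(row_errors),
            row_errors,
        )

    # unit conversion and below-detection handling for configured analytes
    for analyte, bd in bd_flags.items():
        unit = units.get(analyte, "mol/L")
        ok = ~np.isnan(out[analyte].to_numpy())
        out.loc[ok, analyte] = [
            to_molar(v, analyte, unit) for v in out.loc[ok, analyte]
        ]
        flag_col = f"{analyte}_bd"
        if flag_col in raw.columns:
            bd = bd | raw[flag_col].str.strip().str.lower().isin(
                {"true", "1", "yes"}
            ).to_numpy()
        out[flag_col] = bd
        sub = impute_below_detection(analyte, bd_policy)
        out.loc[bd, analyte] = np.nan if sub is None else sub

    bad_t = out["temperature"].notna() & ~out["temperature"].between(0, 100)
    bad_ph = out["ph"].notna() & ~out["ph"].between(0, 14)
    problems = [
        f"line {i + 2}: temperature out of [0, 100]" for i in out.index[bad_t]
    ] + [f"line {i + 2}: pH out of [0, 14]" for i in out.index[bad_ph]]
    if problems:
        raise SchemaError(
            f"{len(problems)} out-of-range values:\n" + "\n".join(problems),
            problems,
        )
    return out[[c for c in SCHEMA_COLUMNS if c in out.columns]]


def write_samples(samples: pd.DataFrame, path) -> None:
    """Write a sample table in the canonical CSV schema."""
    cols = [c for c in SCHEMA_COLUMNS if c in samples.columns]
    extra = [c for c in samples.columns if c not in cols]
    samples[cols + extra].to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: str
    output_dir: str
    fraction_filter: str = "both"  # CL | IPL | both
    ri_include_cren: bool = True
    acidity_mode: str = "fixed7"
    predictors: Sequence[str] = GEOCHEM_PREDICTORS
    responses: Sequence[str] = ("cren_fraction", "ri_with_cren")
    loess_span: float = 0.75
    loess_degree: int = 2
    ph_bin_width: float = 0.5
    temp_bin_width: float = 5.0
    units: dict = field(default_factory=dict)
    bd_policy: str = "half_dl"
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)
        if self.fraction_filter not in ("CL", "IPL", "both"):
            raise ValueError("fraction_filter must be CL, IPL or both")
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")


def run_pipeline(config: RunConfig) -> dict:
    """Execute indices → screen → search → binning/LOESS and persist outputs.

    Returns the per-stage tables; each is also written under the output
    directory together with ``manifest.json`` (config echo, version, row
    counts) so a run can be reproduced exactly. A stage failure raises with
    the stage name after persisting a ``FAILED_<stage>`` marker.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "read"
    try:
        samples = read_samples(
            config.input_path, units=config.units, bd_policy=config.bd_policy
        )
        if config.fraction_filter != "both":
            samples = samples[
                samples["fraction_label"] == config.fraction_filter
            ].reset_index(drop=True)

        stage = "indices"
        table = add_index_columns(samples)
        table.to_csv(outdir / "indices.csv", index=False)
        results["indices"] = table

        stage = "screen"
        preds = [
            p for p in config.predictors if table[p].notna().sum() >= 3
        ]
        scr = screen_all(table, config.responses, preds)
        scr.to_csv(outdir / "screen.csv", index=False)
        results["screen"] = scr

        stage = "search"
        response = (
            "cren_fraction" if "cren_fraction" in config.responses
            else list(config.responses)[0]
        )
        reports = {}
        for resp in config.responses:
            rep = search(table, resp, preds)
            reports[resp] = rep
        frames = []
        for resp, rep in reports.items():
            f = rep.to_frame()
            f.insert(0, "response", resp)
            frames.append(f)
        search_table = pd.concat(frames, ignore_index=True)
        search_table.to_csv(outdir / "model_search.csv", index=False)
        results["search"] = search_table
        results["search_reports"] = reports

        stage = "optima"
        bins_ph = bin_summaries(table, "ph", config.ph_bin_width)
        bins_t = bin_summaries(table, "temperature", config.temp_bin_width)
        bins_ph.to_csv(outdir / "bins_ph.csv", index=False)
        bins_t.to_csv(outdir / "bins_temperature.csv", index=False)
        results["bins_ph"] = bins_ph
        results["bins_temperature"] = bins_t
        optima = {}
        for var, step in (("ph", 0.01), ("temperature", 0.1)):
            est = loess_optimum(
                table[var], table[response],
                span=config.loess_span, degree=config.loess_degree,
                grid_step=step,
            )
            optima[var] = est
            pd.DataFrame(
                {
                    "grid": est.grid,
                    "fitted": est.fitted,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            ).to_csv(outdir / f"loess_{var}.csv", index=False)
        results["optima"] = optima
        results["class_means"] = {
            "acidity": class_means(table, "acidity"),
            "temperature_60": class_means(table, "temperature_60"),
        }
    except Exception as err:
        (outdir / f"FAILED_{stage}").write_text(str(err))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest = {
        "config": {
            **asdict(config),
            "predictors": list(config.predictors),
            "responses": list(config.responses),
        },
        "version": __version__,
        "n_samples": int(len(results["indices"])),
        "n_models": int(len(results["search"])),
        "optima": {
            var: {"x_opt": est.x_opt, "y_opt": est.y_opt,
                  "boundary": bool(est.boundary_flag)}
            for var, est in results["optima"].items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
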