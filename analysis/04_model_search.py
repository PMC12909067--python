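"""Exhaustive all-subsets regression over the seven-analyte panel.

Fits every non-empty subset of the seven geochemical predictors (127
models) for both responses, ranks by adjusted R², and reports the top
significant models with per-predictor inclusion counts.
"""

from pathlib import Path

import pandas as pd

from springlipids import add_index_columns
from springlipids.io import GEOCHEM_PREDICTORS, read_samples
from springlipids.model_search import search

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = add_index_columns(read_samples(RESULTS / "panel41.csv"))
    frames = []
    for response in ("cren_fraction", "ri_with_cren"):
        rep = search(table, response, list(GEOCHEM_PREDICTORS))
        frame = rep.to_frame()
        frame.insert(0, "response", response)
        frames.append(frame)
        best = rep.models[0]
        print(f"{response}: {len(rep.models)} models fitted; best subset "
              f"{'+'.join(best.predictor_subset)} "
              f"(adj R² = {best.adjusted_r2:.3f}, p = {best.model_p_value:.2g})")
        counts = rep.inclusion_counts()
        if counts:
            order = sorted(counts.items(), key=lambda kv: -kv[1])
            print("  inclusion in top significant models: "
                  + ", ".join(f"{k}×{v}" for k, v in order))
    pd.concat(frames, ignore_index=True).to_csv(
        RESULTS / "model_search41.csv", index=False
    )
    print(f"\nwrote {RESULTS / 'model_search41.csv'}")


if __name__ == "__main__":
    main()
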