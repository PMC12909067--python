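"""Spearman and simple-regression screen on the seven-analyte panel.

Tests every (response, predictor) pair of the 41-sample panel: the
crenarchaeol fraction and Ring Index against pH, temperature, DO, SPC,
ORP, Fe(II) and sulphide.
"""

from pathlib import Path

from springlipids import add_index_columns, screen_all
from springlipids.io import GEOCHEM_PREDICTORS, read_samples

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = add_index_columns(read_samples(RESULTS / "panel41.csv"))
    out = screen_all(
        table,
        responses=["cren_fraction", "ri_with_cren"],
        predictors=list(GEOCHEM_PREDICTORS),
    )
    out.to_csv(RESULTS / "screen41.csv", index=False)

    sig = out[out["significant"] & (out["method"] == "spearman")]
    print(f"{len(out)} tests; significant Spearman associations (p < 0.05):")
    print(
        sig[["response", "predictor", "rho", "p_value", "n_used"]]
        .to_string(index=False, float_format=lambda v: f"{v:.3g}")
    )
    print(f"\nwrote {RESULTS / 'screen41.csv'}")


if __name__ == "__main__":
    main()
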