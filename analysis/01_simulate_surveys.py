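"""Generate the two synthetic spring surveys the downstream analyses use.

Writes a compilation-scale survey (n = 300: pH and temperature spanning
the full ranges, bimodal acidity, zero-inflated crenarchaeol) and a
YNP-scale panel (n = 41 with the complete seven-analyte geochemistry) to
results/.
"""

import argparse
from pathlib import Path

from springlipids import SimulationConfig, simulate
from springlipids.synthetic_springs import write_fixture

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    survey = simulate(SimulationConfig(n_samples=300, seed=args.seed))
    write_fixture(survey, RESULTS / "survey300.csv")

    panel = simulate(SimulationConfig(n_samples=41, seed=args.seed + 7))
    write_fixture(panel, RESULTS / "panel41.csv")

    acid = (survey["ph"] < 7).mean()
    print(f"survey300: n=300, {acid:.0%} acidic, "
          f"T {survey.temperature.min():.0f}-{survey.temperature.max():.0f} °C, "
          f"pH {survey.ph.min():.1f}-{survey.ph.max():.1f}")
    print(f"panel41:   n=41 with full geochemistry "
          f"(DO {panel.do_conc.min():.1e}-{panel.do_conc.max():.1e} M)")
    print(f"wrote {RESULTS / 'survey300.csv'} and {RESULTS / 'panel41.csv'}")


if __name__ == "__main__":
    main()
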