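"""Correct the over-reported program panel and derive JSY exposures.

Reads the bulletin-style panel and one-year survey benchmark from
``results/data/``, derives per-district correction factors (the
survey/bulletin ratio of institutional-delivery proportions), applies
each district's factor to every year, and writes the corrected panel
plus the exposure covariates to ``results/harmonized/``.
"""

import argparse
from pathlib import Path

from jsyimpact import data_io
from jsyimpact.harmonize import (
    apply_correction,
    build_exposure_panel,
    derive_correction_factors,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    data = args.results / "data"
    out = args.results / "harmonized"
    out.mkdir(parents=True, exist_ok=True)

    panel = data_io.read_program_panel(data / "program.csv")
    survey = data_io.read_survey(data / "survey.csv")
    factors = derive_correction_factors(panel, survey)
    factors.to_csv(out / "correction_factors.csv", index=False)
    corrected = apply_correction(panel, factors)
    data_io.write_program_panel(corrected, out / "program_corrected.csv")
    exposure = build_exposure_panel(corrected)
    exposure.to_csv(out / "exposure_panel.csv", index=False)

    print(f"correction factors: mean {factors['factor'].mean():.2f}, "
          f"range {factors['factor'].min():.2f}-{factors['factor'].max():.2f}")
    first, last = exposure["year"].min(), exposure["year"].max()
    for y in (first, last):
        sub = exposure[exposure["year"] == y]
        print(f"{y}: institutional {100 * sub['inst_prop'].mean():.1f}%, "
              f"JSY share of deliveries {100 * sub['jsy_prop'].mean():.1f}%")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
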