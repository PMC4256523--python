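"""Generate the default synthetic study scenario.

Writes the multi-source mortality observations, district covariates,
program panel, survey benchmark, membership map and ground truth to
``results/data/``.  The scenario emulates a 12-district state observed
2005-2010 by a biased district bulletin, a division-level survey system
and a state-level gold-standard source, with JSY uptake rising steeply.
"""

import argparse
from pathlib import Path

from jsyimpact import data_io
from jsyimpact.config import ScenarioConfig
from jsyimpact.synth import (
    generate_observations,
    generate_program_panel,
    generate_truth,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=20050)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    out = args.results / "data"
    out.mkdir(parents=True, exist_ok=True)
    scenario = ScenarioConfig(seed=args.seed)
    truth = generate_truth(scenario)
    obs = generate_observations(truth)
    panel, survey, _ = generate_program_panel(truth)

    data_io.write_observations(obs, out / "observations.csv")
    data_io.write_covariates(truth.covariates, out / "covariates.csv")
    data_io.write_program_panel(panel, out / "program.csv")
    data_io.write_survey(survey, out / "survey.csv")
    data_io.write_membership(truth.membership, out / "membership.csv")
    truth.live_births.to_csv(out / "live_births.csv")
    truth.mmr.to_csv(out / "true_mmr.csv")

    state_mmr = (truth.mmr * truth.live_births).sum() \
        / truth.live_births.sum()
    print(f"simulated {len(obs)} observations across "
          f"{len(obs['source_id'].unique())} sources")
    print(f"true state MMR: {state_mmr.iloc[0]:.0f} ({scenario.year_start}) "
          f"-> {state_mmr.iloc[-1]:.0f} ({scenario.year_end})")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
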