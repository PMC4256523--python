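"""Rank candidate estimation models by leave-one-out predictive validity.

Fits a ladder of specifications (toggling covariates, the non-linear
trend component, and source effects) and scores each by the sum of log
conditional predictive ordinates.  Writes the ranking table to
``results/model_selection/``.
"""

import argparse
from pathlib import Path

import pandas as pd

from jsyimpact import data_io
from jsyimpact.model_selection import compare_models, default_model_ladder
from jsyimpact.stage1 import Stage1Spec


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    data = args.results / "data"
    out = args.results / "model_selection"
    out.mkdir(parents=True, exist_ok=True)

    obs = data_io.read_observations(data / "observations.csv")
    covariates = data_io.read_covariates(data / "covariates.csv")
    membership = data_io.read_membership(data / "membership.csv")
    live_births = pd.read_csv(data / "live_births.csv", index_col=0)
    live_births.columns = [int(c) for c in live_births.columns]

    ladder = default_model_ladder(Stage1Spec(draws=500, seed=args.seed))
    table = compare_models(ladder, obs, covariates, live_births, membership,
                           n_draws=10_000)
    table.to_csv(out / "model_comparison.csv", index=False)
    print(table.to_string(index=False))
    best = table.iloc[0]
    print(f"best model by sum log CPO: {best['model']} "
          f"({best['sum_log_cpo']:.1f})")


if __name__ == "__main__":
    main()
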