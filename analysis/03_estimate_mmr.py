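"""Fit the Bayesian spatio-temporal MMR model and export the posterior.

Fits the hierarchical negative-binomial model to the multi-source
observations, writes the per-district-year posterior summary (median and
2.5-97.5% interval), the estimated source effects, and a draw file for
the impact stage to ``results/stage1/``.
"""

import argparse
from pathlib import Path

import pandas as pd

from jsyimpact import data_io
from jsyimpact.pipeline import write_draws
from jsyimpact.stage1 import (
    Stage1Spec,
    fit_stage1,
    percent_change,
    predict_mmr,
    sample_mmr_draws,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--draws", type=int, default=1000)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    data = args.results / "data"
    out = args.results / "stage1"
    out.mkdir(parents=True, exist_ok=True)

    obs = data_io.read_observations(data / "observations.csv")
    covariates = data_io.read_covariates(data / "covariates.csv")
    membership = data_io.read_membership(data / "membership.csv")
    live_births = pd.read_csv(data / "live_births.csv", index_col=0)
    live_births.columns = [int(c) for c in live_births.columns]

    fit = fit_stage1(obs, covariates, live_births, membership,
                     Stage1Spec(draws=args.draws, seed=args.seed))
    posterior = predict_mmr(fit)
    posterior.to_csv(out / "mmr_posterior.csv", index=False)
    fit.source_effects().to_csv(out / "source_effects.csv", index=False)
    surfaces = sample_mmr_draws(fit, fit.n_draws)
    write_draws(surfaces, fit.data.districts, fit.data.years,
                out / "mmr_draws.csv")

    med = posterior.pivot(index="district_id", columns="year",
                          values="median")
    lb = live_births.loc[med.index, med.columns]
    state = (med * lb).sum() / lb.sum()
    print(f"converged: {fit.converged}; "
          f"dispersion estimate {fit.dispersion:.1f}")
    print(f"estimated state MMR {state.iloc[0]:.0f} -> {state.iloc[-1]:.0f} "
          f"(decline {percent_change(state.iloc[0], state.iloc[-1])}%)")
    print(fit.source_effects().to_string(index=False))
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
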