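"""Summarize first-to-last-year changes in MMR and institutional delivery.

Recomputes the headline change summary strictly from the CSV outputs of
the earlier steps and prints it, with the per-district table written to
``results/report/``.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from jsyimpact.reporting import summarize_changes


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    out = args.results / "report"
    out.mkdir(parents=True, exist_ok=True)

    posterior = pd.read_csv(args.results / "stage1" / "mmr_posterior.csv")
    exposure = pd.read_csv(
        args.results / "harmonized" / "exposure_panel.csv")
    live_births = pd.read_csv(args.results / "data" / "live_births.csv",
                              index_col=0)
    live_births.columns = [int(c) for c in live_births.columns]

    summary = summarize_changes(posterior, exposure, live_births)
    summary["districts"].to_csv(out / "district_changes.csv", index=False)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary["state"], fh, indent=2)
    for k, v in summary["state"].items():
        print(f"{k}: {v}")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
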