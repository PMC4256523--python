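"""Output formatting conventions and descriptive change summaries.

All precision rules live here so every table in the pipeline prints the
same way: coefficient estimates to 3 decimals, interval bounds switching
to scientific notation when they would otherwise round to 0.000 (as
needed for expenditure effects on the 1e-06 scale), p-values to 3
decimals with values under 0.0005 printed as "0", headline percent
changes to the nearest integer and district-level ones to one decimal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def format_estimate(value: float) -> str:
    if abs(value) < 5e-4:
        return "0.000"
    return f"{value:.3f}"


def _format_bound(value: float) -> str:
    if value != 0 and abs(value) < 5e-4:
        return f"{value:.3e}"
    return f"{value:.3f}"


def format_interval(lower: float, upper: float) -> str:
    return f"({_format_bound(lower)}, {_format_bound(upper)})"


def format_p(p: float) -> str:
    if p < 5e-4:
        return "0"
    return f"{p:.3f}"


def state_mmr_series(
    posterior: pd.DataFrame, live_births: pd.DataFrame
) -> pd.Series:
    """State-level MMR per year: live-birth-weighted district medians."""
    med = posterior.pivot(index="district_id", columns="year", values="median")
    lb = live_births.loc[med.index, :]
    lb.columns = [int(c) for c in lb.columns]
    lb = lb[med.columns]
    return (med * lb).sum(axis=0) / lb.sum(axis=0)


def summarize_changes(
    posterior: pd.DataFrame,
    exposure_panel: pd.DataFrame,
    live_births: pd.DataFrame,
) -> dict:
    """First-to-last-year changes in MMR and institutional delivery.

    Returns a dict with the state summary (headline rounding, nearest
    integer) and a per-district table (one decimal).
    """
    from jsyimpact.stage1 import percent_change

    years = sorted(posterior["year"].unique())
    y0, y1 = int(years[0]), int(years[-1])
    state = state_mmr_series(posterior, live_births)

    med = posterior.pivot(index="district_id", columns="year", values="median")
    rows = []
    panel = exposure_panel.set_index(["district_id", "year"]).sort_index()
    for d in med.index:
        inst0 = float(panel.loc[(d, y0), "inst_prop"])
        inst1 = float(panel.loc[(d, y1), "inst_prop"])
        rows.append({
            "district_id": d,
            f"mmr_{y0}": round(float(med.at[d, y0]), 1),
            f"mmr_{y1}": round(float(med.at[d, y1]), 1),
            "mmr_decline_pct": percent_change(
                float(med.at[d, y0]), float(med.at[d, y1]), ndigits=1
            ),
            f"inst_prop_{y0}": round(inst0, 3),
            f"inst_prop_{y1}": round(inst1, 3),
            "inst_change_points": round((inst1 - inst0) * 100, 1),
        })
    district_table = pd.DataFrame(rows)

    lbv = live_births.to_numpy(dtype=float)
    total_lb = lbv.sum(axis=0)
    panel_wide = exposure_panel.pivot(
        index="district_id", columns="year", values="inst_prop"
    ).loc[live_births.index]
    inst_state = (panel_wide.to_numpy() * lbv).sum(axis=0) / total_lb
    jsy_wide = exposure_panel.pivot(
        index="district_id", columns="year", values="jsy_prop"
    ).loc[live_births.index]
    jsy_state = (jsy_wide.to_numpy() * lbv).sum(axis=0) / total_lb

    state_summary = {
        "year_first": y0,
        "year_last": y1,
        f"state_mmr_{y0}": round(float(state[y0]), 1),
        f"state_mmr_{y1}": round(float(state[y1]), 1),
        "state_mmr_decline_pct": percent_change(
            float(state[y0]), float(state[y1]), ndigits=0
        ),
        f"state_inst_prop_{y0}_pct": round(float(inst_state[0]) * 100, 1),
        f"state_inst_prop_{y1}_pct": round(float(inst_state[-1]) * 100, 1),
        f"state_jsy_prop_{y0}_pct": round(float(jsy_state[0]) * 100, 1),
        f"state_jsy_prop_{y1}_pct": round(float(jsy_state[-1]) * 100, 1),
        "district_mmr_decline_min_pct": float(
            district_table["mmr_decline_pct"].min()
        ),
        "district_mmr_decline_max_pct": float(
            district_table["mmr_decline_pct"].max()
        ),
    }
    return {"state": state_summary, "districts": district_table}
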