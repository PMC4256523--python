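"""CSV schemas, record validation, and the basic vital-statistics arithmetic.

Three long-format tables flow through the pipeline:

``observations.csv``
    ``unit_id,level,year,source_id,deaths,live_births,mmr`` — one mortality
    record per (unit, year, source).  Either ``deaths`` (with
    ``live_births``) or ``mmr`` must be present, never both.
``covariates.csv``
    ``district_id,tfr,hdi,urban,literacy`` — one row per district.
``program.csv``
    ``district_id,year,jsy_deliveries,institutional_deliveries,
    home_deliveries,total_deliveries,expenditure,anc3``.

Rows violating their invariants are quarantined to a rejects table with a
line-numbered reason, never silently dropped.  Missing values are empty
fields; identifiers are case-sensitive labels; years are calendar years
(fiscal-year sources must be pre-mapped by the user).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger("jsyimpact.data_io")

OBSERVATION_COLUMNS = [
    "unit_id", "level", "year", "source_id", "deaths", "live_births", "mmr",
]
COVARIATE_COLUMNS = ["district_id", "tfr", "hdi", "urban", "literacy"]
PROGRAM_COLUMNS = [
    "district_id", "year", "jsy_deliveries", "institutional_deliveries",
    "home_deliveries", "total_deliveries", "expenditure", "anc3",
]
SURVEY_COLUMNS = ["district_id", "year", "inst_prop"]

LEVELS = ("district", "division", "state")


class SchemaError(ValueError):
    """A file does not match its documented schema."""


class DomainError(ValueError):
    """An argument is outside its mathematical domain."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required columns {missing}")


def derive_live_births(total_deliveries, stillbirth_rate: float):
    """Live births from total deliveries and a stillbirth rate.

    The stillbirth rate is per 1,000 total births, and deliveries are
    taken as total births (multiple births ignored).  Result is rounded
    to the nearest integer.
    """
    if not (0 <= stillbirth_rate < 1000):
        raise DomainError("stillbirth rate must be in [0, 1000)")
    total = np.asarray(total_deliveries, dtype=float)
    if np.any(total < 0):
        raise DomainError("total deliveries must be >= 0")
    out = np.rint(total * (1.0 - stillbirth_rate / 1000.0))
    if np.isscalar(total_deliveries) or np.ndim(total_deliveries) == 0:
        return int(out)
    return out.astype(int)


def compute_mmr(deaths, live_births):
    """Maternal mortality ratio: deaths per 100,000 live births."""
    lb = np.asarray(live_births, dtype=float)
    if np.any(lb <= 0):
        raise DomainError("live_births must be > 0 to compute an MMR")
    d = np.asarray(deaths, dtype=float)
    if np.any(d < 0):
        raise DomainError("deaths must be >= 0")
    out = d / lb * 1e5
    if np.ndim(out) == 0:
        return float(out)
    return out


def _validate_observation_rows(
    df: pd.DataFrame, year_range: tuple[int, int] | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    reasons = []
    has_deaths = df["deaths"].notna()
    has_lb = df["live_births"].notna()
    has_mmr = df["mmr"].notna()
    for i in df.index:
        row_reasons = []
        if df.at[i, "level"] not in LEVELS:
            row_reasons.append(f"unknown level {df.at[i, 'level']!r}")
        if has_deaths[i] and has_mmr[i]:
            row_reasons.append("ambiguous record: both deaths and mmr present")
        elif has_deaths[i] and not has_lb[i]:
            row_reasons.append("deaths present without live_births")
        elif not has_deaths[i] and not has_mmr[i]:
            row_reasons.append("neither deaths nor mmr present")
        if has_deaths[i] and df.at[i, "deaths"] < 0:
            row_reasons.append("negative deaths")
        if has_lb[i] and df.at[i, "live_births"] <= 0:
            row_reasons.append("non-positive live_births")
        if has_mmr[i] and df.at[i, "mmr"] < 0:
            row_reasons.append("negative mmr")
        if year_range is not None and not (
            year_range[0] <= df.at[i, "year"] <= year_range[1]
        ):
            row_reasons.append(
                f"year {df.at[i, 'year']} outside range {year_range}"
            )
        reasons.append("; ".join(row_reasons))
    reasons = pd.Series(reasons, index=df.index)
    bad = reasons != ""
    rejects = df[bad].copy()
    # +2: one for the header line, one for 0- vs 1-based indexing
    rejects.insert(0, "line", rejects.index + 2)
    rejects["reason"] = reasons[bad]
    return df[~bad].copy(), rejects


def read_observations(
    path,
    year_range: tuple[int, int] | None = None,
    return_rejects: bool = False,
):
    """Read and validate a mortality observations CSV.

    Invalid rows are quarantined with a line-numbered reason and logged;
    pass ``return_rejects=True`` to receive ``(valid, rejects)``.
    """
    df = pd.read_csv(path)
    _require_columns(df, OBSERVATION_COLUMNS, "observations")
    df = df[OBSERVATION_COLUMNS]
    if df.empty:
        log.warning("observations file %s is empty (header only)", path)
        rejects = df.copy()
        rejects.insert(0, "line", [])
        rejects["reason"] = []
        return (df, rejects) if return_rejects else df
    valid, rejects = _validate_observation_rows(df, year_range)
    for _, r in rejects.iterrows():
        log.warning(
            "observations %s line %d rejected: %s", path, r["line"], r["reason"]
        )
    return (valid, rejects) if return_rejects else valid


def write_observations(df: pd.DataFrame, path) -> None:
    _require_columns(df, OBSERVATION_COLUMNS, "observations")
    df[OBSERVATION_COLUMNS].to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COVARIATE_COLUMNS, "covariates")
    df = df[COVARIATE_COLUMNS]
    bad = (
        (df["hdi"] < 0) | (df["hdi"] > 1)
        | (df["urban"] < 0) | (df["urban"] > 100)
        | (df["literacy"] < 0) | (df["literacy"] > 100)
        | (df["tfr"] <= 0)
    )
    if bad.any():
        raise SchemaError(
            f"covariates: {int(bad.sum())} rows outside valid ranges "
            f"(lines {[int(i) + 2 for i in df.index[bad]]})"
        )
    if df["district_id"].duplicated().any():
        raise SchemaError("covariates: duplicate district_id")
    return df


def write_covariates(df: pd.DataFrame, path) -> None:
    _require_columns(df, COVARIATE_COLUMNS, "covariates")
    df[COVARIATE_COLUMNS].to_csv(path, index=False)


def read_program_panel(path, return_rejects: bool = False):
    """Read and validate the district-year program panel."""
    df = pd.read_csv(path)
    _require_columns(df, PROGRAM_COLUMNS, "program panel")
    df = df[PROGRAM_COLUMNS]
    reasons = []
    for i in df.index:
        row_reasons = []
        jsy = df.at[i, "jsy_deliveries"]
        inst = df.at[i, "institutional_deliveries"]
        home = df.at[i, "home_deliveries"]
        total = df.at[i, "total_deliveries"]
        if not (jsy <= inst <= total):
            row_reasons.append("need jsy <= institutional <= total deliveries")
        if (
            pd.notna(home)
            and abs((inst + home) - total) > 0.5
        ):
            row_reasons.append("institutional + home != total deliveries")
        if pd.notna(df.at[i, "anc3"]) and not (0 <= df.at[i, "anc3"] <= 100):
            row_reasons.append("anc3 outside [0, 100]")
        reasons.append("; ".join(row_reasons))
    reasons = pd.Series(reasons, index=df.index)
    bad = reasons != ""
    rejects = df[bad].copy()
    rejects.insert(0, "line", rejects.index + 2)
    rejects["reason"] = reasons[bad]
    for _, r in rejects.iterrows():
        log.warning(
            "program panel %s line %d rejected: %s", path, r["line"], r["reason"]
        )
    valid = df[~bad].copy()
    return (valid, rejects) if return_rejects else valid


def write_program_panel(df: pd.DataFrame, path) -> None:
    _require_columns(df, PROGRAM_COLUMNS, "program panel")
    df[PROGRAM_COLUMNS].to_csv(path, index=False)


def read_survey(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SURVEY_COLUMNS, "survey benchmark")
    df = df[SURVEY_COLUMNS]
    bad = (df["inst_prop"] <= 0) | (df["inst_prop"] > 1)
    if bad.any():
        raise SchemaError("survey benchmark: inst_prop must be in (0, 1]")
    return df


def write_survey(df: pd.DataFrame, path) -> None:
    _require_columns(df, SURVEY_COLUMNS, "survey benchmark")
    df[SURVEY_COLUMNS].to_csv(path, index=False)


MEMBERSHIP_COLUMNS = ["district_id", "division_id"]


def read_membership(path) -> dict[str, str]:
    """District -> division mapping from a two-column CSV."""
    df = pd.read_csv(path)
    _require_columns(df, MEMBERSHIP_COLUMNS, "membership")
    if df["district_id"].duplicated().any():
        raise SchemaError("membership: a district appears more than once")
    return dict(zip(df["district_id"], df["division_id"]))


def write_membership(membership: dict[str, str], path) -> None:
    pd.DataFrame(
        {"district_id": list(membership), "division_id": list(membership.values())}
    ).to_csv(path, index=False)
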