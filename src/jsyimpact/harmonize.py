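"""Envelope benchmarking, delivery-proportion correction, and JSY exposure.

Two harmonization steps precede the mortality model and the impact
regression:

1. *Envelope benchmarking (raking)*: district death counts are scaled
   proportionally within each (envelope unit, year) cell so that their
   sum equals the count reported by a more trusted higher-level source
   (division or state).
2. *Delivery-proportion correction*: bulletin-reported institutional
   (and home) delivery proportions are multiplied by a per-district
   correction factor — the ratio of the survey-reported to the
   bulletin-reported proportion in a single benchmark year — applied
   constantly across years, on the assumption that the bulletin's
   relative bias is stable over the study period.

The exposure panel then carries the regression covariates
``jsy_prop = JSY deliveries / total deliveries`` and
``njsy_prop = (institutional - JSY) / total deliveries``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from jsyimpact.data_io import DomainError

log = logging.getLogger("jsyimpact.harmonize")


class MappingError(ValueError):
    """A district is not mapped to an envelope unit."""


class InvariantError(ValueError):
    """A derived quantity violates a panel invariant."""


@dataclass(frozen=True)
class CorrectionFactor:
    """Per-district survey/bulletin institutional-delivery ratio."""

    district_id: str
    factor: float
    benchmark_year: int
    exceeds_one: bool = False


def _force_exact_sum(scaled: np.ndarray, env: float) -> np.ndarray:
    """Make ``scaled.sum() == env`` bit-exactly.

    Proportional scaling leaves a float-rounding residual of a few ulp.
    The residual is assigned to the largest district; because a single
    coarse correction can straddle the target's rounding bin, the
    smallest element is then walked one ulp at a time until the sum
    lands exactly on the envelope value.
    """
    if not scaled.size:
        return scaled
    scaled = scaled.copy()
    if scaled.sum() == env:
        return scaled
    # try absorbing the residual in each element in turn, walking a few
    # ulp around the corrected value (sequential rounding in the sum can
    # skip values, so a single fixed adjustment is not always enough)
    order = np.argsort(scaled)[::-1]
    for k in order:
        cand = scaled.copy()
        cand[k] = scaled[k] + (env - scaled.sum())
        for _ in range(128):
            resid = env - cand.sum()
            if resid == 0:
                return cand
            cand[k] = np.nextafter(cand[k], np.inf if resid > 0 else -np.inf)
    log.warning("raking residual of %.3g could not be zeroed",
                env - scaled.sum())
    return scaled


def benchmark_to_envelope(
    district_deaths: pd.DataFrame,
    envelope: pd.DataFrame,
    membership: dict[str, str],
) -> pd.DataFrame:
    """Rake district death counts to higher-level envelope totals.

    Parameters
    ----------
    district_deaths : wide table, index district_id, one column per year.
    envelope : wide table, index envelope unit id, one column per year.
        Cells may be NaN where the envelope source did not report.
    membership : maps each district to exactly one envelope unit.

    Within each (unit, year) cell the districts are scaled by
    ``envelope / sum`` so their sum matches the envelope exactly; the
    float-rounding residual is assigned to the largest district.  A
    zero-sum group under a positive envelope falls back to an equal
    split (with a warning); NaN envelope cells leave the districts
    untouched.
    """
    unmapped = [d for d in district_deaths.index if d not in membership]
    if unmapped:
        raise MappingError(f"districts not mapped to an envelope unit: {unmapped}")
    out = district_deaths.astype(float).copy()
    for unit in envelope.index:
        members = [d for d in out.index if membership[d] == unit]
        if not members:
            continue
        for year in district_deaths.columns:
            if year not in envelope.columns:
                continue
            env = envelope.at[unit, year]
            if pd.isna(env):
                continue
            block = out.loc[members, year].to_numpy(dtype=float)
            total = block.sum()
            if total > 0:
                scaled = block * (env / total)
            elif env > 0:
                log.warning(
                    "envelope %s year %s: district sum is zero; "
                    "splitting %s equally across %d districts",
                    unit, year, env, len(members),
                )
                scaled = np.full(len(members), env / len(members))
            else:
                scaled = block
            scaled = _force_exact_sum(scaled, float(env))
            out.loc[members, year] = scaled
    return out


def derive_correction_factor(
    bulletin_prop: float,
    survey_prop: float,
    district_id: str,
    benchmark_year: int,
) -> CorrectionFactor:
    """Survey/bulletin ratio of institutional-delivery proportions.

    A factor above 1 (survey exceeding bulletin) is allowed but flagged,
    since the usual situation is bulletin over-reporting.
    """
    if not (0 < bulletin_prop <= 1):
        raise DomainError("bulletin proportion must be in (0, 1]")
    if not (0 < survey_prop <= 1):
        raise DomainError("survey proportion must be in (0, 1]")
    factor = survey_prop / bulletin_prop
    exceeds = factor > 1
    if exceeds:
        log.warning(
            "district %s: correction factor %.3f exceeds 1 "
            "(survey above bulletin)", district_id, factor,
        )
    return CorrectionFactor(district_id, factor, benchmark_year, exceeds)


def derive_correction_factors(
    panel: pd.DataFrame, survey: pd.DataFrame
) -> pd.DataFrame:
    """Correction factors for every district from panel + survey benchmark.

    Uses the bulletin institutional proportion of the survey's benchmark
    year.  Returns an audit table ``district_id, factor, benchmark_year,
    exceeds_one``.
    """
    rows = []
    for _, srow in survey.iterrows():
        year = int(srow["year"])
        sub = panel[(panel["district_id"] == srow["district_id"])
                    & (panel["year"] == year)]
        if sub.empty:
            raise MappingError(
                f"no panel row for district {srow['district_id']} in "
                f"benchmark year {year}"
            )
        bulletin = float(
            sub["institutional_deliveries"].iloc[0] / sub["total_deliveries"].iloc[0]
        )
        cf = derive_correction_factor(
            bulletin, float(srow["inst_prop"]), srow["district_id"], year
        )
        rows.append(
            {
                "district_id": cf.district_id,
                "factor": cf.factor,
                "benchmark_year": cf.benchmark_year,
                "exceeds_one": cf.exceeds_one,
            }
        )
    return pd.DataFrame(rows)


def apply_correction(panel: pd.DataFrame, factors: pd.DataFrame) -> pd.DataFrame:
    """Apply each district's single factor to every year of the panel.

    Institutional (and JSY) delivery counts are rescaled by the factor,
    home deliveries absorb the difference, and total deliveries are
    unchanged, so the institutional proportion is multiplied by the
    factor in every year (constant relative bias).  Counts become floats;
    corrected proportions above 1 are clipped with a warning.
    """
    fmap = factors.set_index("district_id")["factor"]
    missing = set(panel["district_id"]) - set(fmap.index)
    if missing:
        raise MappingError(f"no correction factor for districts: {sorted(missing)}")
    out = panel.copy()
    out = out.astype({c: float for c in
                      ("jsy_deliveries", "institutional_deliveries",
                       "home_deliveries", "total_deliveries")})
    f = out["district_id"].map(fmap).to_numpy(dtype=float)
    total = out["total_deliveries"].to_numpy(dtype=float)
    inst = out["institutional_deliveries"].to_numpy(dtype=float) * f
    jsy = out["jsy_deliveries"].to_numpy(dtype=float) * f
    over = inst > total
    if over.any():
        log.warning(
            "corrected institutional proportion exceeds 1 for %d "
            "district-years; clipping", int(over.sum()),
        )
        jsy = np.where(over, jsy * total / inst, jsy)
        inst = np.minimum(inst, total)
    out["institutional_deliveries"] = inst
    out["jsy_deliveries"] = jsy
    out["home_deliveries"] = total - inst
    return out


def build_exposure_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Derive the exposure covariates from a (corrected) program panel.

    Returns ``district_id, year, jsy_prop, njsy_prop, inst_prop,
    expenditure, anc3`` with ``jsy_prop + njsy_prop == inst_prop``.
    """
    total = panel["total_deliveries"].to_numpy(dtype=float)
    if np.any(total <= 0):
        raise DomainError("total_deliveries must be > 0 to derive proportions")
    jsy = panel["jsy_deliveries"].to_numpy(dtype=float)
    inst = panel["institutional_deliveries"].to_numpy(dtype=float)
    bad = jsy > inst + 1e-9
    if bad.any():
        where = panel.loc[bad, ["district_id", "year"]].itertuples(index=False)
        names = ", ".join(f"{d}/{y}" for d, y in where)
        raise InvariantError(
            f"JSY deliveries exceed institutional deliveries for: {names}"
        )
    out = pd.DataFrame(
        {
            "district_id": panel["district_id"].to_numpy(),
            "year": panel["year"].to_numpy(),
            "jsy_prop": jsy / total,
            "njsy_prop": (inst - jsy) / total,
            "inst_prop": inst / total,
            "expenditure": panel["expenditure"].to_numpy(dtype=float),
            "anc3": panel["anc3"].to_numpy(dtype=float),
        }
    )
    return out
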