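"""Synthetic multi-source district mortality data with known ground truth.

Emulates the data situation of a state-level maternal-mortality study that
must synthesize administrative and survey sources: district death counts
from a biased, incomplete health bulletin, aggregated counts from
division- and state-level gold-standard systems, census-style district
covariates, and a program panel whose institutional-delivery proportions
are over-reported relative to a one-off survey benchmark.

Ground truth (``SyntheticTruth``) records the true MMR surface, source
biases and the true program-effect coefficient, so that every downstream
stage — harmonization, the spatio-temporal count model, and the
draw-propagated impact regression — can be tested for parameter recovery
without any external data.

Randomness is organised as one master seed spawning independent
substreams per purpose (truth / observations / program panel), so adding
an observation source never perturbs the generated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from jsyimpact.config import (
    COVARIATE_CENTERS,
    ConfigError,
    ScenarioConfig,
)

STATE_ID = "STATE"

# fixed spawn keys: 0 = truth, 1 = observations, 2 = program panel
_TRUTH, _OBS, _PANEL = 0, 1, 2


def _substream(config: ScenarioConfig, purpose: int) -> np.random.Generator:
    child = np.random.SeedSequence(config.seed).spawn(3)[purpose]
    return np.random.default_rng(child)


def district_ids(config: ScenarioConfig) -> list[str]:
    return [f"D{i + 1:02d}" for i in range(config.n_districts)]


def division_ids(config: ScenarioConfig) -> list[str]:
    return [f"V{i + 1}" for i in range(config.n_divisions)]


def district_division_map(config: ScenarioConfig) -> dict[str, str]:
    """Assign districts to divisions in contiguous blocks, as even as possible."""
    dids = district_ids(config)
    vids = division_ids(config)
    base, extra = divmod(config.n_districts, config.n_divisions)
    mapping: dict[str, str] = {}
    k = 0
    for j, vid in enumerate(vids):
        size = base + (1 if j < extra else 0)
        for _ in range(size):
            mapping[dids[k]] = vid
            k += 1
    return mapping


@dataclass
class SyntheticTruth:
    """Ground truth of one generated scenario.

    All panel attributes are DataFrames indexed by district id with one
    column per calendar year.
    """

    config: ScenarioConfig
    districts: list[str]
    divisions: list[str]
    membership: dict[str, str]
    covariates: pd.DataFrame          # district_id, tfr, hdi, urban, literacy
    log_mmr: pd.DataFrame
    mmr: pd.DataFrame                 # deaths per 100,000 live births
    deliveries: pd.DataFrame          # total deliveries (~ total births)
    live_births: pd.DataFrame
    expected_deaths: pd.DataFrame     # mmr * live_births / 1e5 (unrounded)
    inst_prop: pd.DataFrame           # true institutional-delivery proportion
    jsy_share: pd.DataFrame           # true JSY share of institutional deliveries
    jsy_prop: pd.DataFrame            # JSY deliveries / total deliveries
    anc3: pd.DataFrame                # percent with >= 3 antenatal visits
    true_betas: dict = field(default_factory=dict)
    true_source_biases: dict = field(default_factory=dict)
    district_effects: pd.DataFrame | None = None  # intercept/slope per district

    @property
    def years(self) -> list[int]:
        return list(self.log_mmr.columns)


def _interp_curve(start: float, end: float, n: int) -> np.ndarray:
    return np.linspace(start, end, n)


def _district_curves(
    state_curve: np.ndarray, offsets: np.ndarray, growths: np.ndarray,
    tc: np.ndarray,
) -> np.ndarray:
    """Per-district proportion curves around the state curve.

    Each district shifts the state curve on the logit scale by a level
    offset plus a growth deviation per (centred) year, so districts
    differ both in where uptake starts and in how fast it rises.  With
    zero offsets and growths the state curve is returned untouched, so
    degenerate configurations keep exact endpoint values (including 0
    and 1).
    """
    if np.all(offsets == 0) and np.all(growths == 0):
        return np.tile(state_curve, (len(offsets), 1))
    p = np.clip(state_curve, 1e-9, 1 - 1e-9)
    return expit(
        logit(p)[None, :] + offsets[:, None] + growths[:, None] * tc[None, :]
    )


def generate_truth(config: ScenarioConfig) -> SyntheticTruth:
    """Generate the latent state of one scenario, deterministically per seed.

    The true log MMR of district *d* in year *t* is::

        baseline + covariate effects . (x_d - centre)
                 + division intercept + district intercept
                 + (mean slope + division slope + district slope) * (t - tbar)
                 + smooth non-linear perturbation (RW2 draw)
                 + program_effect * jsy_prop[d, t]
    """
    rng = _substream(config, _TRUTH)
    dids = district_ids(config)
    vids = division_ids(config)
    membership = district_division_map(config)
    years = np.asarray(config.years)
    T = len(years)
    tc = years - years.mean()

    # census-style covariates
    cov = pd.DataFrame(
        {
            "district_id": dids,
            "tfr": rng.uniform(2.5, 4.5, size=len(dids)),
            "hdi": rng.uniform(0.30, 0.65, size=len(dids)),
            "urban": rng.uniform(8.0, 45.0, size=len(dids)),
            "literacy": rng.uniform(40.0, 78.0, size=len(dids)),
        }
    )

    a_div = rng.normal(0.0, config.division_intercept_sd, size=len(vids))
    a_dis = rng.normal(0.0, config.district_intercept_sd, size=len(dids))
    z_div = rng.normal(0.0, config.trend.division_slope_sd, size=len(vids))
    z_dis = rng.normal(0.0, config.trend.slope_sd, size=len(dids))
    div_index = np.array([vids.index(membership[d]) for d in dids])
    slope = config.trend.slope_mean + z_div[div_index] + z_dis

    # smooth non-linear state-level perturbation: RW2 draw with the constant
    # and linear parts projected out, so it is orthogonal to the trend terms
    if config.trend.nonlinear_scale > 0 and T >= 3:
        steps = rng.normal(0.0, config.trend.nonlinear_scale, size=T - 2)
        xi = np.zeros(T)
        for t in range(2, T):
            xi[t] = 2 * xi[t - 1] - xi[t - 2] + steps[t - 2]
        basis = np.vstack([np.ones(T), tc]).T
        proj = basis @ np.linalg.lstsq(basis, xi, rcond=None)[0]
        xi = xi - proj
    else:
        xi = np.zeros(T)

    # program uptake
    up = config.uptake
    inst_state = _interp_curve(up.inst_prop_start, up.inst_prop_end, T)
    share_state = _interp_curve(up.jsy_share_start, up.jsy_share_end, T)
    if up.district_sd > 0:
        inst_off = rng.normal(0.0, up.district_sd, size=len(dids))
        share_off = rng.normal(0.0, up.district_sd, size=len(dids))
    else:
        inst_off = np.zeros(len(dids))
        share_off = np.zeros(len(dids))
    if up.district_growth_sd > 0:
        inst_gro = rng.normal(0.0, up.district_growth_sd, size=len(dids))
        share_gro = rng.normal(0.0, up.district_growth_sd, size=len(dids))
    else:
        inst_gro = np.zeros(len(dids))
        share_gro = np.zeros(len(dids))
    inst = _district_curves(inst_state, inst_off, inst_gro, tc)
    share = _district_curves(share_state, share_off, share_gro, tc)
    jsy_prop = inst * share

    anc3_state = _interp_curve(up.anc3_start, up.anc3_end, T)
    if up.anc3_district_sd > 0:
        anc3 = np.clip(
            anc3_state[None, :]
            + rng.normal(0.0, up.anc3_district_sd, size=len(dids))[:, None],
            0.0,
            100.0,
        )
    else:
        anc3 = np.tile(anc3_state, (len(dids), 1))

    x_tfr = cov["tfr"].to_numpy() - COVARIATE_CENTERS["tfr"]
    x_hdi = cov["hdi"].to_numpy() - COVARIATE_CENTERS["hdi"]
    eff = config.covariate_effects
    cov_term = eff.get("tfr", 0.0) * x_tfr + eff.get("hdi", 0.0) * x_hdi

    log_mmr = (
        config.baseline_log_mmr_mean
        + cov_term[:, None]
        + a_div[div_index][:, None]
        + a_dis[:, None]
        + slope[:, None] * tc[None, :]
        + xi[None, :]
        + config.program_effect * jsy_prop
    )

    if config.population_spread > 0:
        pop = config.population_per_district * rng.uniform(
            1 - config.population_spread,
            1 + config.population_spread,
            size=len(dids),
        )
    else:
        pop = np.full(len(dids), config.population_per_district)
    deliveries = np.rint(pop * config.crude_birth_rate / 1000.0)
    deliveries_panel = np.tile(deliveries[:, None], (1, T))
    live_births = np.rint(
        deliveries_panel * (1.0 - config.stillbirth_rate / 1000.0)
    )

    mmr = np.exp(log_mmr)
    expected_deaths = mmr * live_births / 1e5
    if not np.all(mmr > 0):
        raise ConfigError("generated MMR must be positive everywhere")

    def panel(arr: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(arr, index=pd.Index(dids, name="district_id"),
                            columns=list(years))

    effects = pd.DataFrame(
        {
            "district_id": dids,
            "intercept": a_div[div_index] + a_dis,
            "slope": slope,
        }
    )

    return SyntheticTruth(
        config=config,
        districts=dids,
        divisions=vids,
        membership=membership,
        covariates=cov,
        log_mmr=panel(log_mmr),
        mmr=panel(mmr),
        deliveries=panel(deliveries_panel),
        live_births=panel(live_births),
        expected_deaths=panel(expected_deaths),
        inst_prop=panel(inst),
        jsy_share=panel(share),
        jsy_prop=panel(jsy_prop),
        anc3=panel(anc3),
        true_betas={
            "baseline_log_mmr": config.baseline_log_mmr_mean,
            "program_effect": config.program_effect,
            "slope_mean": config.trend.slope_mean,
            **{f"beta_{k}": v for k, v in config.covariate_effects.items()},
        },
        true_source_biases={s.source_id: s.bias for s in config.sources},
        district_effects=effects,
    )


def _aggregate(truth: SyntheticTruth, level: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Unit ids, expected deaths and live births aggregated to a level."""
    ed = truth.expected_deaths.to_numpy()
    lb = truth.live_births.to_numpy()
    if level == "district":
        return list(truth.districts), ed, lb
    if level == "division":
        units = truth.divisions
        rows_e, rows_b = [], []
        for vid in units:
            members = [i for i, d in enumerate(truth.districts)
                       if truth.membership[d] == vid]
            rows_e.append(ed[members].sum(axis=0))
            rows_b.append(lb[members].sum(axis=0))
        return list(units), np.array(rows_e), np.array(rows_b)
    if level == "state":
        return [STATE_ID], ed.sum(axis=0, keepdims=True), lb.sum(axis=0, keepdims=True)
    raise ConfigError(f"unknown level {level!r}")


def generate_observations(
    truth: SyntheticTruth, config: ScenarioConfig | None = None
) -> pd.DataFrame:
    """Draw the multi-source mortality observations table.

    Reported deaths for a unit-year are negative-binomial with mean
    ``bias * (true deaths aggregated to the source's level)`` and the
    configured dispersion (``overdispersion = inf`` gives Poisson noise);
    unit-years are then dropped independently with probability
    ``1 - coverage``.  Sources flagged ``reports_mmr_directly`` publish
    the resulting MMR and the denominator instead of the count.
    """
    config = config or truth.config
    master = _substream(config, _OBS)
    streams = master.spawn(len(config.sources))
    years = truth.years
    rows = []
    for spec, rng in zip(config.sources, streams):
        units, ed, lb = _aggregate(truth, spec.level)
        mean = spec.bias * ed
        k = config.overdispersion
        if np.isinf(k):
            deaths = rng.poisson(mean)
        else:
            # NB as Gamma-Poisson mixture, mean m, size k
            deaths = rng.poisson(rng.gamma(k, mean / k))
        keep = rng.random(size=mean.shape) <= spec.coverage
        for i, unit in enumerate(units):
            for j, year in enumerate(years):
                if not keep[i, j]:
                    continue
                rec = {
                    "unit_id": unit,
                    "level": spec.level,
                    "year": int(year),
                    "source_id": spec.source_id,
                    "deaths": np.nan,
                    "live_births": float(lb[i, j]),
                    "mmr": np.nan,
                }
                if spec.reports_mmr_directly:
                    rec["mmr"] = deaths[i, j] / lb[i, j] * 1e5
                else:
                    rec["deaths"] = float(deaths[i, j])
                rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=["unit_id", "level", "year", "source_id",
                 "deaths", "live_births", "mmr"],
    )


def generate_program_panel(
    truth: SyntheticTruth, config: ScenarioConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Bulletin-style program panel, survey benchmark, and true factors.

    Returns ``(panel, survey, factors)``.  The panel reports
    institutional-delivery proportions inflated by ``1/factor_d`` where
    the true correction factor of each district is drawn uniformly from
    the configured range; the survey benchmark reports the true
    institutional proportion for the single benchmark year.  Expenditure
    (in lakh) is proportional to reported JSY deliveries with
    multiplicative log-normal noise.
    """
    config = config or truth.config
    rng = _substream(config, _PANEL)
    up = config.uptake
    dids = truth.districts
    years = truth.years

    factors = rng.uniform(up.factor_low, up.factor_high, size=len(dids))
    rows = []
    total = truth.deliveries.to_numpy()
    inst_true = truth.inst_prop.to_numpy()
    share_true = truth.jsy_share.to_numpy()
    anc3 = truth.anc3.to_numpy()
    noise = rng.lognormal(
        mean=-0.5 * np.log1p(up.expenditure_noise_cv**2),
        sigma=np.sqrt(np.log1p(up.expenditure_noise_cv**2)),
        size=inst_true.shape,
    )
    for i, d in enumerate(dids):
        for j, year in enumerate(years):
            inst_rep = min(inst_true[i, j] / factors[i], 0.98)
            inst_n = np.rint(inst_rep * total[i, j])
            jsy_n = np.rint(share_true[i, j] * inst_n)
            exp_lakh = jsy_n * up.expenditure_per_delivery_lakh * noise[i, j]
            rows.append(
                {
                    "district_id": d,
                    "year": int(year),
                    "jsy_deliveries": jsy_n,
                    "institutional_deliveries": inst_n,
                    "home_deliveries": total[i, j] - inst_n,
                    "total_deliveries": total[i, j],
                    "expenditure": round(exp_lakh, 3),
                    "anc3": round(anc3[i, j], 2),
                }
            )
    panel = pd.DataFrame(rows)
    survey = pd.DataFrame(
        {
            "district_id": dids,
            "year": int(up.benchmark_year),
            "inst_prop": inst_true[:, years.index(up.benchmark_year)]
            if up.benchmark_year in years
            else inst_true[:, 0],
        }
    )
    factor_df = pd.DataFrame({"district_id": dids, "true_factor": factors})
    return panel, survey, factor_df


def true_exposure_panel(truth: SyntheticTruth) -> pd.DataFrame:
    """Exposure panel built from the ground truth, bypassing reporting bias.

    Matches the schema produced by the harmonization step
    (``district_id, year, jsy_prop, njsy_prop, inst_prop, expenditure,
    anc3``) but uses the true proportions that generated the outcomes.
    Used to study the impact-regression stage under correct exposure
    measurement, isolating its statistical properties from the
    bulletin-reporting error chain.
    """
    up = truth.config.uptake
    rows = []
    for i, d in enumerate(truth.districts):
        for year in truth.years:
            inst = float(truth.inst_prop.at[d, year])
            jsy = float(truth.jsy_prop.at[d, year])
            jsy_n = jsy * float(truth.deliveries.at[d, year])
            rows.append({
                "district_id": d,
                "year": int(year),
                "jsy_prop": jsy,
                "njsy_prop": inst - jsy,
                "inst_prop": inst,
                "expenditure": jsy_n * up.expenditure_per_delivery_lakh,
                "anc3": float(truth.anc3.at[d, year]),
            })
    return pd.DataFrame(rows)


def posterior_like_draws(
    truth: SyntheticTruth,
    n_draws: int,
    sd: float,
    seed: int,
    common_sd: float = 0.0,
) -> np.ndarray:
    """Emulated stage-1 posterior: MMR surfaces around the true surface.

    Each draw *m* is ``exp(true log MMR + e_m + c_m)`` with ``e_m``
    independent N(0, sd^2) per district-year and ``c_m`` a draw-level
    common shift N(0, common_sd^2) inducing posterior correlation across
    the surface.  Used to study the draw-propagation stage in isolation
    from the count model.

    Returns an array of shape ``(n_draws, n_districts, n_years)`` on the
    MMR (not log) scale.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    rng = np.random.default_rng(seed)
    base = np.broadcast_to(
        truth.log_mmr.to_numpy()[None, :, :],
        (n_draws,) + truth.log_mmr.shape,
    )
    e = rng.normal(0.0, sd, size=base.shape) if sd > 0 else 0.0
    c = (
        rng.normal(0.0, common_sd, size=(n_draws, 1, 1))
        if common_sd > 0
        else 0.0
    )
    return np.exp(base + e + c)
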