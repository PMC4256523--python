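"""End-to-end orchestration: simulate -> harmonize -> estimate -> impact.

A pipeline run is driven by one configuration mapping (YAML on disk or a
dict) and writes every intermediate table as CSV to the output
directory, plus a run manifest recording the configuration hash, all
seeds, input-file digests and every warning any stage raised.  The
report step recomputes its summary numbers from the output CSVs rather
than from in-memory state, so the written artifacts are the single
source of truth.

Configuration keys::

    scenario:  ScenarioConfig fields -> simulate synthetic inputs
    inputs:    paths {observations, covariates, program, survey,
               membership} -> use existing files instead of simulating
    stillbirth_rate: used to derive live births when reading real inputs
    stage1:    Stage1Spec fields (draws, trend, covariates, ...)
    stage2:    Stage2Spec fields (n_draws, ...)
    exposures: list of exposures to assess (default both)
    model_selection: true to also rank the default model ladder by CPO
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from jsyimpact import data_io, reporting
from jsyimpact.config import ScenarioConfig
from jsyimpact.harmonize import (
    apply_correction,
    build_exposure_panel,
    derive_correction_factors,
)
from jsyimpact.model_selection import compare_models, default_model_ladder
from jsyimpact.stage1 import Stage1Spec, fit_stage1, predict_mmr, sample_mmr_draws
from jsyimpact.stage2 import (
    Stage2Spec,
    district_slope_report,
    fit_propagated,
    make_coefficient_table,
)
from jsyimpact.synth import (
    generate_observations,
    generate_program_panel,
    generate_truth,
)

log = logging.getLogger("jsyimpact.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.records: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.records.append(f"{record.name}: {record.getMessage()}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False
    return _Ctx()


def write_draws(draws: np.ndarray, districts, years, path) -> None:
    """MMR draw surfaces as a long CSV (draw, district_id, year, mmr)."""
    n, D, T = draws.shape
    idx = pd.MultiIndex.from_product(
        [range(n), districts, years], names=["draw", "district_id", "year"]
    )
    pd.DataFrame({"mmr": draws.reshape(-1)}, index=idx).reset_index().to_csv(
        path, index=False
    )


def read_draws(path) -> tuple[np.ndarray, list[str], list[int]]:
    df = pd.read_csv(path)
    districts = list(pd.unique(df["district_id"]))
    years = sorted(df["year"].unique())
    n = df["draw"].nunique()
    arr = (
        df.set_index(["draw", "district_id", "year"])["mmr"]
        .unstack(["district_id", "year"])
        .loc[:, pd.MultiIndex.from_product([districts, years])]
        .to_numpy()
        .reshape(n, len(districts), len(years))
    )
    return arr, districts, [int(y) for y in years]


def run_pipeline(config, out_dir, seed: int | None = None) -> Path:
    """Execute the full pipeline; returns the output directory.

    ``config`` is a mapping or a path to a YAML file.  ``seed``
    overrides every stage seed (scenario, posterior draws, stage-2
    sampling) derived as ``seed``, ``seed+1``, ``seed+2``.
    """
    t_start = time.time()
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    config = dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    collector = _WarningCollector()
    root = logging.getLogger("jsyimpact")
    root.addHandler(collector)
    try:
        return _run(config, out, seed, collector, t_start)
    finally:
        root.removeHandler(collector)


def _run(config, out, seed, collector, t_start) -> Path:
    manifest: dict = {
        "config_hash": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "started_unix": t_start,
        "stages": [],
    }

    # ---- inputs: simulate or read -------------------------------------
    if "inputs" in config:
        with _stage("inputs"):
            paths = {k: Path(v) for k, v in config["inputs"].items()}
            missing = {k: str(p) for k, p in paths.items() if not p.exists()}
            if missing:
                raise FileNotFoundError(f"missing input files: {missing}")
            obs = data_io.read_observations(paths["observations"])
            covariates = data_io.read_covariates(paths["covariates"])
            panel = data_io.read_program_panel(paths["program"])
            survey = data_io.read_survey(paths["survey"])
            membership = data_io.read_membership(paths["membership"])
            sbr = float(config.get("stillbirth_rate", 15.0))
            lb_wide = panel.pivot(
                index="district_id", columns="year", values="total_deliveries"
            )
            live_births = pd.DataFrame(
                data_io.derive_live_births(lb_wide.to_numpy(), sbr),
                index=lb_wide.index, columns=lb_wide.columns,
            )
            manifest["input_digests"] = {
                k: _sha256(p) for k, p in paths.items()
            }
            truth = None
    else:
        with _stage("simulate"):
            scen = dict(config.get("scenario", {}))
            if seed is not None:
                scen["seed"] = int(seed)
            scenario = ScenarioConfig.from_dict(scen)
            truth = generate_truth(scenario)
            obs = generate_observations(truth)
            panel, survey, _ = generate_program_panel(truth)
            covariates = truth.covariates
            membership = truth.membership
            live_births = truth.live_births
            data_io.write_observations(obs, out / "observations.csv")
            data_io.write_covariates(covariates, out / "covariates.csv")
            data_io.write_program_panel(panel, out / "program.csv")
            data_io.write_survey(survey, out / "survey.csv")
            data_io.write_membership(membership, out / "membership.csv")
            truth.mmr.to_csv(out / "true_mmr.csv")
            manifest["scenario_seed"] = scenario.seed
            manifest["input_digests"] = {
                name: _sha256(out / f"{name}.csv")
                for name in ("observations", "covariates", "program", "survey")
            }
    live_births.to_csv(out / "live_births.csv")
    manifest["stages"].append("inputs")

    # ---- harmonize ----------------------------------------------------
    with _stage("harmonize"):
        factors = derive_correction_factors(panel, survey)
        factors.to_csv(out / "correction_factors.csv", index=False)
        corrected = apply_correction(panel, factors)
        data_io.write_program_panel(corrected, out / "program_corrected.csv")
        exposure = build_exposure_panel(corrected)
        exposure.to_csv(out / "exposure_panel.csv", index=False)
    manifest["stages"].append("harmonize")

    # ---- stage 1: estimate MMR ---------------------------------------
    with _stage("estimate-mmr"):
        s1cfg = dict(config.get("stage1", {}))
        if "covariates" in s1cfg:
            s1cfg["covariates"] = tuple(s1cfg["covariates"])
        if seed is not None:
            s1cfg["seed"] = int(seed) + 1
        spec1 = Stage1Spec(**s1cfg)
        fit1 = fit_stage1(obs, covariates, live_births, membership, spec1)
        if not fit1.converged:
            log.warning("stage-1 fit flagged non-converged; results retained")
        posterior = predict_mmr(fit1)
        posterior.to_csv(out / "mmr_posterior.csv", index=False)
        fit1.source_effects().to_csv(out / "source_effects.csv", index=False)
        manifest["stage1_seed"] = spec1.seed
        manifest["stage1_converged"] = bool(fit1.converged)
    manifest["stages"].append("estimate-mmr")

    # ---- optional model comparison -----------------------------------
    if config.get("model_selection", False):
        with _stage("evaluate-models"):
            ladder = default_model_ladder(spec1)
            ranking = compare_models(
                ladder, obs, covariates, live_births, membership
            )
            ranking.to_csv(out / "model_comparison.csv", index=False)
        manifest["stages"].append("evaluate-models")

    # ---- stage 2: impact on both exposures ---------------------------
    s2cfg = dict(config.get("stage2", {}))
    if seed is not None:
        s2cfg["seed"] = int(seed) + 2
    exposures = config.get("exposures", ["jsy_prop", "expenditure"])
    n_draws = int(s2cfg.pop("n_draws", 200))
    seed2 = int(s2cfg.pop("seed", 0))
    for exposure_name in exposures:
        with _stage(f"assess-impact[{exposure_name}]"):
            spec2 = Stage2Spec(
                exposure=exposure_name, n_draws=n_draws, seed=seed2, **s2cfg
            )
            draws = sample_mmr_draws(fit1, n_draws, seed=seed2)
            result = fit_propagated(
                draws, covariates, exposure,
                spec2, districts=fit1.data.districts, years=fit1.data.years,
            )
            result.coefficients.to_csv(
                out / f"coefficients_{exposure_name}.csv", index=False
            )
            make_coefficient_table(result).to_csv(
                out / f"coefficients_{exposure_name}_formatted.csv", index=False
            )
            slopes, summary = district_slope_report(result)
            slopes.to_csv(
                out / f"district_slopes_{exposure_name}.csv", index=False
            )
            result.draw_estimates.to_csv(
                out / f"draw_coefficients_{exposure_name}.csv", index=False
            )
            log.info("%s: %s", exposure_name, summary)
        manifest["stages"].append(f"assess-impact[{exposure_name}]")
    manifest["stage2_seed"] = seed2
    manifest["stage2_n_draws"] = n_draws

    # ---- report (recomputed from the written CSVs) --------------------
    with _stage("report"):
        summary = write_report(out)
        manifest["report"] = summary["state"]
    manifest["stages"].append("report")

    manifest["warnings"] = list(collector.records)
    manifest["elapsed_seconds"] = round(time.time() - t_start, 3)
    from jsyimpact import __version__

    manifest["package_version"] = __version__
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def write_report(out_dir) -> dict:
    """Build the change summary strictly from the output CSVs."""
    out = Path(out_dir)
    posterior = pd.read_csv(out / "mmr_posterior.csv")
    exposure = pd.read_csv(out / "exposure_panel.csv")
    live_births = pd.read_csv(out / "live_births.csv", index_col=0)
    live_births.columns = [int(c) for c in live_births.columns]
    summary = reporting.summarize_changes(posterior, exposure, live_births)
    summary["districts"].to_csv(out / "district_changes.csv", index=False)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary["state"], fh, indent=2)
    return summary
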