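"""End-to-end orchestration: simulate -> describe -> fit -> compare.

A pipeline run covers a single city (each city is modelled separately); a
batch wrapper can loop cities.  Every artifact records the run seed and a
hash of the configuration, stage completion is tracked in a manifest so
an interrupted run can resume, and all randomness derives from the one
configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import descriptive
from .decline import FitResult, OptimizerConfig, PriorConfig, fit_decline
from .gravity import compare_bic, fit_gravity_decline
from .io_prep import ZipTable, build_covariates, load_trip_panel, write_trip_panel
from .summer import fit_summer
from .synthetic import SimConfig, generate_city, simulate_decline_panel, simulate_summer_panel

log = logging.getLogger("odmobility")

STAGES = ("simulate", "describe", "fit-decline", "fit-summer", "fit-gravity", "compare")


@dataclass
class RunConfig:
    """Configuration of one single-city pipeline run."""

    outdir: str = "run"
    seed: int = 0
    n_zips: int = 20
    n_weeks: int = 9
    baseline_weeks: int = 4
    summer_n_weeks: int = 13
    censor_threshold: int = 50
    data_loss_weeks: tuple[int, ...] = ()
    reference_quartile: int = 2
    quartile_period: str = "all"  # "all" | "baseline"
    use_case_covariate: bool = True
    priors: dict = field(default_factory=dict)
    optimizer: dict = field(default_factory=dict)
    stages: tuple[str, ...] = STAGES
    plot: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("data_loss_weeks", "stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = asdict(self)
        d.pop("outdir")
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mpath = outdir / "manifest.json"
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "artifacts": {},
    }
    if resume and mpath.exists():
        prev = json.loads(mpath.read_text())
        if prev.get("config_hash") == manifest["config_hash"]:
            manifest = prev

    sim = SimConfig(
        n_zips=config.n_zips,
        n_weeks=config.n_weeks,
        baseline_weeks=config.baseline_weeks,
        seed=config.seed,
        censor_threshold=config.censor_threshold,
        data_loss_weeks=frozenset(config.data_loss_weeks),
        summer_n_weeks=config.summer_n_weeks,
    )
    priors = PriorConfig(**config.priors)
    optimizer = OptimizerConfig(**config.optimizer)
    paths = {name: outdir / name for name in (
        "zips.csv", "trips.csv", "cases.csv", "summer_trips.csv", "truth.json",
        "descriptive.csv", "fit_decline.json", "fit_summer.json",
        "fit_gravity.json", "compare.csv",
    )}

    def done(stage: str) -> bool:
        return resume and manifest["stages"].get(stage) == "completed"

    def complete(stage: str, artifacts: list[str]) -> None:
        manifest["stages"][stage] = "completed"
        for a in artifacts:
            manifest["artifacts"][a] = str(paths[a])
        _write_manifest(outdir, manifest)
        log.info("stage %s completed", stage)

    if "simulate" in config.stages and not done("simulate"):
        ziptable = generate_city(sim)
        panel, truth = simulate_decline_panel(ziptable, sim)
        spanel, struth = simulate_summer_panel(
            ziptable, truth["log_r"], sim, covariates=truth["covariates"]
        )
        ziptable.to_csv(paths["zips.csv"])
        write_trip_panel(panel, paths["trips.csv"])
        write_trip_panel(spanel, paths["summer_trips.csv"])
        truth["cases"].to_csv(paths["cases.csv"], index=False)
        truth_payload = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "c": list(map(float, truth["c"])),
            "beta": {k: float(v) for k, v in truth["beta"].items()},
            "beta_a": {k: float(v) for k, v in truth["beta_a"].items()},
            "summer_beta0": float(struth["beta0"]),
            "summer_beta": {k: float(v) for k, v in struth["beta"].items()},
            "summer_beta_a": {k: float(v) for k, v in struth["beta_a"].items()},
        }
        paths["truth.json"].write_text(json.dumps(truth_payload, indent=2, sort_keys=True))
        complete("simulate", ["zips.csv", "trips.csv", "cases.csv", "summer_trips.csv", "truth.json"])

    # shared inputs for later stages
    ziptable = ZipTable.from_csv(paths["zips.csv"])
    panel = load_trip_panel(
        paths["trips.csv"], config.censor_threshold, frozenset(config.data_loss_weeks)
    )
    cases = pd.read_csv(paths["cases.csv"], dtype={"county_id": str}) if config.use_case_covariate else None
    qperiod = set(range(1, config.baseline_weeks + 1)) if config.quartile_period == "baseline" else None
    covs = build_covariates(
        panel, ziptable, cases,
        reference_quartile=config.reference_quartile,
        quartile_period=qperiod,
    )

    if "describe" in config.stages and not done("describe"):
        table = descriptive.descriptive_table(panel, ziptable, covs, city_id=f"sim-{config.seed}")
        table.to_csv(paths["descriptive.csv"], index=False)
        if config.plot:
            series = descriptive.stratified_series(panel, "age")
            descriptive.plot_relative_series(series, str(outdir / "relative_mobility.png"))
        complete("describe", ["descriptive.csv"])

    if "fit-decline" in config.stages and not done("fit-decline"):
        fit = fit_decline(panel, covs, ziptable, priors, config.baseline_weeks,
                          max_week=config.n_weeks, optimizer=optimizer)
        fit.meta.update(seed=config.seed, config_hash=config.config_hash())
        fit.to_json(paths["fit_decline.json"])
        log.info("decline fit: %d params, converged=%s", fit.n_params, fit.converged)
        complete("fit-decline", ["fit_decline.json"])

    if "fit-summer" in config.stages and not done("fit-summer"):
        base_fit = FitResult.from_json(paths["fit_decline.json"])
        spanel = load_trip_panel(paths["summer_trips.csv"], config.censor_threshold)
        spanel = replace(spanel, resolution="aggregate", n_weeks=config.summer_n_weeks)
        fit = fit_summer(spanel, base_fit.estimates["log_r"], covs, ziptable, priors,
                         optimizer=optimizer)
        fit.meta.update(seed=config.seed, config_hash=config.config_hash())
        fit.to_json(paths["fit_summer.json"])
        complete("fit-summer", ["fit_summer.json"])

    if "fit-gravity" in config.stages and not done("fit-gravity"):
        fit = fit_gravity_decline(panel, covs, ziptable, priors, config.baseline_weeks,
                                  max_week=config.n_weeks, optimizer=optimizer)
        fit.meta.update(seed=config.seed, config_hash=config.config_hash())
        fit.to_json(paths["fit_gravity.json"])
        complete("fit-gravity", ["fit_gravity.json"])

    if "compare" in config.stages and not done("compare"):
        fits = [FitResult.from_json(paths["fit_decline.json"]),
                FitResult.from_json(paths["fit_gravity.json"])]
        compare_bic(fits).to_csv(paths["compare.csv"], index=False)
        complete("compare", ["compare.csv"])

    return manifest
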