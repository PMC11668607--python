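"""End-to-end workflow orchestration from a single YAML config.

Stages run in the fixed order of the workflow: simulate (or ingest) →
quality filter → density thinning → IDW interpolation (+ optional
density experiment) → correlation screening → model cross-validation →
wall-to-wall AGB map. Each stage writes its outputs (open text formats
only) before the next starts, and a run manifest records config hash,
per-file digests and timings. One global seed deterministically derives
per-stage seeds, so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import allometry, gedi_io, interpolation, modeling, synthetic
from .raster import write_ascii_grid
from .synthetic import METRIC_SCHEMA, _derive_seed

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config"]

logger = logging.getLogger("gediagb.pipeline")

REQUIRED_SECTIONS = ("mode", "seed", "filter", "thinning", "interpolation", "modeling")


class ConfigError(ValueError):
    """Missing or invalid pipeline configuration."""


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``load_config`` for the YAML shape)."""

    mode: str
    seed: int
    output_dir: Path
    scene: dict = field(default_factory=dict)  # synthetic-mode generator knobs
    inputs: dict = field(default_factory=dict)  # real-mode file paths
    filter: dict = field(default_factory=dict)
    thinning: dict = field(default_factory=dict)
    interpolation: dict = field(default_factory=dict)
    experiment: dict | None = None
    modeling: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        for section in REQUIRED_SECTIONS:
            if section not in cfg:
                raise ConfigError(f"config is missing the {section!r} section")
        mode = cfg["mode"]
        if mode not in ("synthetic", "real"):
            raise ConfigError(f"mode must be 'synthetic' or 'real', got {mode!r}")
        if mode == "real" and "inputs" not in cfg:
            raise ConfigError("real mode requires an 'inputs' section")
        return cls(
            mode=mode,
            seed=int(cfg["seed"]),
            output_dir=Path(cfg.get("output_dir", "gediagb_run")),
            scene=dict(cfg.get("scene", {})),
            inputs=dict(cfg.get("inputs", {})),
            filter=dict(cfg["filter"]),
            thinning=dict(cfg["thinning"]),
            interpolation=dict(cfg["interpolation"]),
            experiment=dict(cfg["experiment"]) if "experiment" in cfg else None,
            modeling=dict(cfg["modeling"]),
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


@dataclass
class RunManifest:
    """What a run produced: digests make reruns comparable bit for bit."""

    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)  # stage -> {files: {name: sha256}, seconds}
    completed: bool = False

    def record(self, stage: str, files: dict[str, Path], seconds: float) -> None:
        digests = {
            str(name): hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in files.items()
        }
        self.stages[stage] = {"files": digests, "seconds": round(seconds, 3)}

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "completed": self.completed,
                "stages": self.stages,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def comparable(self) -> dict:
        """Manifest content with timings stripped (for determinism checks)."""
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "completed": self.completed,
            "stages": {s: v["files"] for s, v in self.stages.items()},
        }


def _stage_seed(config: RunConfig, stage: str) -> int:
    return _derive_seed(config.seed, f"stage:{stage}")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full workflow; outputs land under ``config.output_dir``.

    Returns the manifest; a stage failure raises after the manifest (with
    the stages completed so far) is written to ``manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(
            {k: str(v) for k, v in vars(config).items()}, sort_keys=True
        ).encode()
    ).hexdigest()
    manifest = RunManifest(config_hash=cfg_hash, seed=config.seed)

    try:
        # --- stage 1: acquire footprints and plots -----------------------
        t0 = time.perf_counter()
        if config.mode == "synthetic":
            scene = synthetic.default_scene(
                seed=_stage_seed(config, "scene"), **config.scene
            )
            footprints = scene.footprints
            plot_df = allometry.write_plot_agb_csv(scene.plots, out / "plots.csv")
            extent = scene.extent
        else:
            footprints = gedi_io.read_footprint_csv(config.inputs["footprints_csv"])
            plots = allometry.read_plot_csv(config.inputs["plots_csv"])
            plot_df = allometry.write_plot_agb_csv(plots, out / "plots.csv")
            extent = (
                footprints["x"].min(),
                footprints["y"].min(),
                footprints["x"].max(),
                footprints["y"].max(),
            )
        gedi_io.write_footprint_csv(footprints, out / "footprints_raw.csv")
        logger.info("acquired %d footprints, %d plots", len(footprints), len(plot_df))
        manifest.record(
            "acquire",
            {"footprints_raw.csv": out / "footprints_raw.csv", "plots.csv": out / "plots.csv"},
            time.perf_counter() - t0,
        )

        # --- stage 2: quality filter -------------------------------------
        t0 = time.perf_counter()
        criteria = gedi_io.FilterCriteria(
            quality_flag_required=int(config.filter.get("quality_flag", 1)),
            degrade_flag_required=int(config.filter.get("degrade_flag", 0)),
            sensitivity_min=float(config.filter.get("sensitivity_min", 0.9)),
        )
        filtered, report = gedi_io.filter_footprints(footprints, criteria)
        gedi_io.write_footprint_csv(filtered, out / "footprints_filtered.csv")
        report.to_json(out / "filter_report.json")
        logger.info("filter kept %d / %d shots", report.n_kept, report.n_input)
        manifest.record(
            "filter",
            {
                "footprints_filtered.csv": out / "footprints_filtered.csv",
                "filter_report.json": out / "filter_report.json",
            },
            time.perf_counter() - t0,
        )

        # --- stage 3: thinning --------------------------------------------
        t0 = time.perf_counter()
        thinned = gedi_io.thin_footprints(
            filtered,
            interval=int(config.thinning.get("interval", 100)),
            offset=int(config.thinning.get("offset", 0)),
            random_offset=bool(config.thinning.get("random_offset", False)),
            seed=_stage_seed(config, "thinning"),
        )
        gedi_io.write_footprint_csv(thinned, out / "footprints_thinned.csv")
        logger.info("thinning retained %d shots", len(thinned))
        manifest.record(
            "thin",
            {"footprints_thinned.csv": out / "footprints_thinned.csv"},
            time.perf_counter() - t0,
        )

        # --- stage 4: interpolation (+ optional density experiment) ------
        t0 = time.perf_counter()
        interp_cfg = config.interpolation
        variables = list(
            interp_cfg.get("variables", [m for m in METRIC_SCHEMA if m in thinned.columns])
        )
        cell = float(interp_cfg.get("cell_size_m", 30.0))
        power = float(interp_cfg.get("power", 2.0))
        n_nb = int(interp_cfg.get("n_neighbors", 12))
        radius = interp_cfg.get("max_search_radius_m")
        rasters = {}
        raster_files: dict[str, Path] = {}
        for var in variables:
            grid = interpolation.idw_rasterize(
                thinned, var, extent, cell, power, n_nb, radius
            )
            rasters[var] = grid
            p = out / f"raster_{var}.asc"
            write_ascii_grid(grid, p)
            raster_files[p.name] = p
        if config.experiment is not None:
            result = interpolation.run_density_experiment(
                filtered,
                intervals=config.experiment.get("intervals", (10, 30, 50, 70, 100)),
                variables=config.experiment.get("variables", variables),
                fraction=float(config.experiment.get("fraction", 0.7)),
                power=power,
                n_neighbors=n_nb,
                max_search_radius_m=radius,
                seed=_stage_seed(config, "experiment"),
            )
            interpolation.write_experiment_result(
                result, out / "density_experiment.csv", out / "density_experiment.json"
            )
            raster_files["density_experiment.csv"] = out / "density_experiment.csv"
        manifest.record("interpolate", raster_files, time.perf_counter() - t0)

        # --- stage 5: screen, fit, map ------------------------------------
        t0 = time.perf_counter()
        fm, exclusions = modeling.extract_features(plot_df, rasters)
        exclusions.to_csv(out / "plot_exclusions.csv", index=False)
        top = modeling.correlation_screen(fm, top_k=int(config.modeling.get("top_k", 5)))
        top.to_csv(out / "correlation_screen.csv", index=False)
        selected = list(top["variable"])
        cfg = modeling.ModelConfig(
            algorithm=config.modeling.get("algorithm", "rf"),
            seed=_stage_seed(config, "modeling"),
        )
        cv = modeling.fit_and_cross_validate(
            fm,
            cfg,
            n_folds=int(config.modeling.get("n_folds", 10)),
            features=selected,
        )
        cv.to_json(out / "cv_result.json")
        est = modeling.make_estimator(cfg)
        est.fit(fm[selected].to_numpy(float), fm["agb_t_per_hm2"].to_numpy(float))
        agb_map, summary = modeling.predict_map(est, rasters, selected)
        write_ascii_grid(agb_map, out / "agb_map.asc")
        (out / "agb_summary.json").write_text(json.dumps(summary.to_dict(), indent=1))
        logger.info(
            "model %s: mean out-of-fold R2=%.3f RMSE=%.2f; map mean %.2f t/hm2",
            cfg.algorithm,
            cv.mean_r2,
            cv.mean_rmse,
            summary.mean,
        )
        manifest.record(
            "model",
            {
                "correlation_screen.csv": out / "correlation_screen.csv",
                "cv_result.json": out / "cv_result.json",
                "agb_map.asc": out / "agb_map.asc",
                "agb_summary.json": out / "agb_summary.json",
            },
            time.perf_counter() - t0,
        )
        manifest.completed = True
    finally:
        manifest.to_json(out / "manifest.json")
    return manifest
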