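"""Config-driven orchestration of the atosense analyses.

Five run modes, all reproducible from (config, seed):

* ``simulate``   — integrate the model over a time grid, export the trajectory
* ``sweep``      — steady-state k_ap dose-response curve (+ Hill fit)
* ``morris``     — elementary-effects screening heatmap
* ``synthstudy`` — synthetic cytometry study + Hill recovery fit
* ``fit``        — Hill fit of an existing dose-response CSV

Every run writes a ``manifest.json`` carrying the seed, a hash of the
resolved configuration, package/library versions and wall metadata, so any
artifact can be traced back to the exact inputs that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cytometry import (
    DEFAULT_CONC_GRID,
    FIXTURES,
    IDENTITY_CALIBRATION,
    generate_study,
    load_fixture,
)
from .doseresponse import DoseResponseCurve, default_kap_grid, fit_hill, sweep_dose_response
from .model import TCSParameters, trajectory_frame
from .morris import MorrisDesign, ParameterSpace, default_space, rank_parameters, run_morris

__all__ = ["RunConfig", "ConfigError", "run", "MODES"]

MODES = ("simulate", "sweep", "morris", "synthstudy", "fit")
log = logging.getLogger("atosense")


class ConfigError(ValueError):
    """The run configuration violates the schema."""


class RunConfig:
    """Validated run configuration.

    Required: ``mode``.  Optional: ``params`` (YAML/JSON parameter file),
    ``space``/``design`` (morris), ``fixture`` (synthstudy: a known name or
    a JSON path), ``curve`` (fit: CSV path), plus mode-specific knobs.
    """

    def __init__(self, mode: str, seed: int = 0, out_dir="runs", workers: int = 1, **options):
        if mode not in MODES:
            raise ConfigError(f"field 'mode' must be one of {MODES}, got {mode!r}")
        if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
            raise ConfigError("field 'seed' must be an integer")
        if workers < 1:
            raise ConfigError("field 'workers' must be >= 1")
        self.mode = mode
        self.seed = int(seed)
        self.out_dir = Path(out_dir)
        self.workers = int(workers)
        self.options = options

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        data = yaml.safe_load(p.read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config must be a YAML mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "mode" not in data:
            raise ConfigError("field 'mode' is required")
        return cls(**data)

    def resolved(self) -> dict:
        return {
            "mode": self.mode, "seed": self.seed, "out_dir": str(self.out_dir),
            "workers": self.workers, **self.options,
        }


def _config_hash(resolved: dict) -> str:
    return hashlib.sha256(json.dumps(resolved, sort_keys=True).encode()).hexdigest()[:16]


def _load_params(cfg: RunConfig) -> TCSParameters:
    path = cfg.options.get("params")
    if path is None:
        return TCSParameters()
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"parameter file not found: {p}")
    return TCSParameters.from_file(p)


def _write_manifest(cfg: RunConfig, artifacts: dict, extra: dict, started: float) -> dict:
    resolved = cfg.resolved()
    manifest = {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "config": resolved,
        "config_hash": _config_hash(resolved),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "versions": {
            "atosense": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "wall_seconds": round(time.time() - started, 3),
        **extra,
    }
    path = cfg.out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["manifest_path"] = str(path)
    return manifest


def run(config: RunConfig) -> dict:
    """Execute one stage; returns the artifact manifest."""
    started = time.time()
    cfg = config
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    params = _load_params(cfg)
    artifacts: dict = {}
    extra: dict = {}

    if cfg.mode == "simulate":
        t_end = float(cfg.options.get("t_end", 1000.0))
        n_t = int(cfg.options.get("n_times", 200))
        frame = trajectory_frame(params, np.linspace(0.0, t_end, n_t))
        path = cfg.out_dir / "trajectory.csv"
        frame.to_csv(path, index=False)
        artifacts["trajectory"] = path

    elif cfg.mode == "sweep":
        grid = cfg.options.get("kap_grid")
        curve = sweep_dose_response(params, None if grid is None else np.asarray(grid, float))
        curve_path = cfg.out_dir / "dose_response.csv"
        curve.to_csv(curve_path)
        fit = fit_hill(curve)
        fit_path = cfg.out_dir / "hill_fit.json"
        fit.to_json(fit_path)
        artifacts.update(curve=curve_path, fit=fit_path)
        extra["hill"] = {k: fit.to_dict()[k] for k in ("fmin", "fmax", "K", "n", "fold_change")}

    elif cfg.mode == "morris":
        space = (
            ParameterSpace.from_dict(yaml.safe_load(Path(cfg.options["space"]).read_text()))
            if "space" in cfg.options else default_space(params)
        )
        design_opts = cfg.options.get("design", {})
        design = MorrisDesign(
            p=int(design_opts.get("p", 4)),
            R=int(design_opts.get("R", 1000)),
            r=int(design_opts.get("r", 50)),
            seed=cfg.seed,
        )
        grid = cfg.options.get("kap_grid")
        result = run_morris(
            space, design, params,
            kap_grid=None if grid is None else np.asarray(grid, float),
            workers=cfg.workers,
        )
        tidy_path = cfg.out_dir / "morris.csv"
        result.to_frame().to_csv(tidy_path, index=False)
        heat_path = cfg.out_dir / "morris_heatmap.csv"
        result.heatmap_frame().to_csv(heat_path, index_label="parameter")
        artifacts.update(morris=tidy_path, heatmap=heat_path)
        extra["rankings"] = rank_parameters(result, exclude=cfg.options.get("exclude", ()))
        n_missing = int((result.n_effects < design.r).sum())
        extra["cells_with_missing_effects"] = n_missing
        log.info("morris: %d cells had missing elementary effects", n_missing)

    elif cfg.mode == "synthstudy":
        fixture_opt = cfg.options.get("fixture", "asah0")
        fixture = FIXTURES[fixture_opt] if fixture_opt in FIXTURES else load_fixture(fixture_opt)
        grid = cfg.options.get("conc_grid")
        study = generate_study(
            fixture,
            conc_grid=None if grid is None else np.asarray(grid, float),
            replicates=int(cfg.options.get("replicates", 3)),
            noise_cv=float(cfg.options.get("noise_cv", 0.05)),
            seed=cfg.seed,
            calibration=IDENTITY_CALIBRATION,
        )
        wells_path = cfg.out_dir / "wells.csv"
        study.to_frame().to_csv(wells_path, index=False)
        fit = study.fit()
        fit_path = cfg.out_dir / "hill_fit.json"
        fit.to_json(fit_path)
        artifacts.update(wells=wells_path, fit=fit_path)
        extra["hill"] = {k: fit.to_dict()[k] for k in ("fmin", "fmax", "K", "n", "fold_change")}

    elif cfg.mode == "fit":
        curve_path = cfg.options.get("curve")
        if curve_path is None or not Path(curve_path).exists():
            raise ConfigError(f"fit mode needs an existing 'curve' CSV, got {curve_path!r}")
        curve = DoseResponseCurve.from_csv(curve_path)
        fit = fit_hill(curve, n_fixed=cfg.options.get("n_fixed"))
        fit_path = cfg.out_dir / "hill_fit.json"
        fit.to_json(fit_path)
        artifacts["fit"] = fit_path
        extra["hill"] = {k: fit.to_dict()[k] for k in ("fmin", "fmax", "K", "n", "fold_change")}

    return _write_manifest(cfg, artifacts, extra, started)
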