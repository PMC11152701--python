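"""End-to-end pipeline orchestration with a reproducible run manifest.

Stages: simulate (synthetic cubes + reference pigment panels) → extract
(calibrate/segment/average/trim) → prep (outlier screen + 3:1:1 split) →
train (the requested model families) → evaluate (metrics table, optional
linear-fit plots) → explain (Grad-CAM++ maps + peak/valley reports for CNN
models). Intermediates are flat CSV/JSON so each stage can be re-run in
isolation; the manifest records the config, per-stage outputs and checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataprep, interpret, models, pipeline, synthcube
from .containers import PIGMENTS, VNIR, LeafspecError, SpectraMatrix

logger = logging.getLogger(__name__)

DEFAULT_FAMILIES = ("pls", "bpnn", "cnn")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through JSON/YAML."""

    out_dir: str = "run"
    camera: str = VNIR
    condition: str = synthcube.UNPACKAGED
    periods: tuple = synthcube.DEFAULT_PERIODS[synthcube.UNPACKAGED]
    leaves: int = 15
    days: int = 2
    n_bands: int = 224
    seed: int = 0
    scene: dict = field(default_factory=dict)
    thresholds: dict | None = None  # per-pigment overrides; None → auto
    families: tuple = DEFAULT_FAMILIES
    modes: tuple = (models.SINGLE, models.MULTI)
    cnn_variant: str | None = None  # None → camera default
    net: dict = field(default_factory=dict)  # NetConfig overrides
    component_grid: tuple = tuple(range(1, 13))
    make_plots: bool = False
    skip_simulate: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def design(self) -> synthcube.StudyDesign:
        return synthcube.StudyDesign(
            self.condition, tuple(self.periods), self.leaves, self.days,
            (self.camera,), self.seed,
        )


def _checksum(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(asdict(config), default=list)),
                      "stages": {}}

    # -- simulate ----------------------------------------------------------
    cubes_dir = out / "cubes" / config.camera
    targets_path = out / "targets.csv"
    if config.skip_simulate:
        if not targets_path.exists() or not cubes_dir.exists():
            raise LeafspecError(
                f"--skip-simulate requires existing inputs: {targets_path} and {cubes_dir}"
            )
        panels = pd.read_csv(targets_path)
    else:
        logger.info("simulate: rendering %s cubes", config.design().n_samples)
        scene = synthcube.SceneConfig(**config.scene) if config.scene else synthcube.SceneConfig()
        panels = synthcube.simulate_cubes(
            config.design(), cubes_dir, camera=config.camera,
            n_bands=config.n_bands, scene=scene,
        )
        panels.to_csv(targets_path, index=False)
    manifest["stages"]["simulate"] = {
        "targets": _checksum(targets_path), "n_samples": len(panels)}

    # -- extract -----------------------------------------------------------
    spectra = pipeline.extract_dataset(cubes_dir)
    spectra_path = out / f"spectra_{config.camera}.csv"
    spectra.to_csv(spectra_path)
    manifest["stages"]["extract"] = {
        "spectra": _checksum(spectra_path), "n_bands": len(spectra.grid)}

    # -- prep --------------------------------------------------------------
    order = panels.set_index("sample_id").loc[spectra.meta["sample_id"]]
    Y = order[list(PIGMENTS)].to_numpy(float)
    thresholds = None
    if config.thresholds is not None:
        thresholds = np.array([config.thresholds[p] for p in PIGMENTS], float)
    report = dataprep.screen_outliers(spectra.spectra, Y, thresholds)
    retained = report.retained_indices
    split = dataprep.split_dataset(len(retained), config.seed)
    pd.DataFrame(
        {
            "sample_id": spectra.meta["sample_id"],
            **{f"residual_{p}": report.residuals[:, j] for j, p in enumerate(PIGMENTS)},
            **{f"flag_{p}": report.flags[:, j] for j, p in enumerate(PIGMENTS)},
            "removed": report.union_flags,
        }
    ).to_csv(out / "outlier_report.csv", index=False)
    with open(out / "split.json", "w") as fh:
        json.dump(split.as_dict(), fh)
    manifest["stages"]["prep"] = {
        "removed": report.removed_count, "retained": int(len(retained)),
        "split": _checksum(out / "split.json"),
    }

    X = spectra.spectra[retained]
    Yr = Y[retained]
    splits = {
        name: (X[idx], Yr[idx])
        for name, idx in (("train", split.train), ("val", split.val), ("test", split.test))
    }

    # -- train -------------------------------------------------------------
    net_cfg = models.NetConfig(**config.net) if config.net else models.NetConfig()
    variant = config.cnn_variant or ("vnir" if config.camera == VNIR else "nir")
    fitted: dict[str, models.FittedModel] = {}
    for family in config.families:
        for mode in config.modes:
            prefix = {"pls": "PLSR", "bpnn": "BPNN", "cnn": "CNN"}[family]
            name = ("ST" if mode == models.SINGLE else "MT") + prefix
            if mode == models.SINGLE:
                for j, pigment in enumerate(PIGMENTS):
                    key = f"{name}_{pigment}"
                    fitted[key] = _fit_one(
                        family, mode, splits, j, (pigment,), config, net_cfg, variant
                    )
            else:
                fitted[name] = _fit_one(
                    family, mode, splits, None, PIGMENTS, config, net_cfg, variant
                )
    logs = {
        name: model.training_log for name, model in fitted.items() if model.training_log
    }
    with open(out / "training_logs.json", "w") as fh:
        json.dump(logs, fh, default=float)
    manifest["stages"]["train"] = {"models": sorted(fitted)}

    # -- evaluate ----------------------------------------------------------
    table = interpret.build_metrics_table(
        fitted, splits, camera=config.camera, condition=config.condition,
    )
    table_path = out / "metrics.csv"
    table.to_csv(table_path, index=False)
    manifest["stages"]["evaluate"] = {"metrics": _checksum(table_path), "rows": len(table)}
    if config.make_plots:
        plots = out / "plots"
        plots.mkdir(exist_ok=True)
        for name, model in fitted.items():
            if model.task_mode == models.MULTI and model.family == "cnn":
                for task in model.tasks:
                    interpret.plot_linear_fits(model, splits, task, plots / f"{name}_{task}.png")

    # -- explain -----------------------------------------------------------
    explain_rows = []
    reports = {}
    X_test = splits["test"][0]
    for name, model in fitted.items():
        if model.family != "cnn":
            continue
        for j, task in enumerate(model.tasks):
            imap = interpret.gradcam_pp_1d(model, X_test, j, grid=spectra.grid)
            explain_rows.append(
                pd.DataFrame({"model": name, "task": task,
                              "wavelength": imap.wavelengths, "weight": imap.weights})
            )
            if not imap.all_zero:
                reports[f"{name}/{task}"] = interpret.peaks_valleys(imap).as_dict()
    if explain_rows:
        pd.concat(explain_rows, ignore_index=True).to_csv(out / "importance_maps.csv", index=False)
        with open(out / "peaks_valleys.json", "w") as fh:
            json.dump(reports, fh)
        manifest["stages"]["explain"] = {
            "maps": _checksum(out / "importance_maps.csv"), "reports": len(reports)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _fit_one(family, mode, splits, column, tasks, config: RunConfig,
             net_cfg: models.NetConfig, variant: str) -> models.FittedModel:
    def _target(Y):
        return Y if column is None else Y[:, [column]]

    X_train, Y_train = splits["train"]
    X_val, Y_val = splits["val"]
    if family == "pls":
        grid = [k for k in config.component_grid if k <= min(X_train.shape[0] - 1, X_train.shape[1])]
        return models.fit_pls(X_train, _target(Y_train), X_val, _target(Y_val),
                              task_mode=mode, component_grid=grid, tasks=tasks)
    if family == "bpnn":
        bp_cfg = models.NetConfig(**{**net_cfg.__dict__, "hidden": 32})
        return models.fit_bpnn(X_train, _target(Y_train), X_val, _target(Y_val),
                               task_mode=mode, config=bp_cfg, seed=config.seed, tasks=tasks)
    if family == "cnn":
        return models.train_cnn(X_train, _target(Y_train), X_val, _target(Y_val),
                                variant=variant, task_mode=mode, config=net_cfg,
                                seed=config.seed, tasks=tasks)
    raise LeafspecError(f"unknown model family {family!r}")
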