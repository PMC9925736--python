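"""End-to-end orchestration: scene → registration → filtering → measurement,
and herd table → models → metrics.

A single :class:`RunConfig` (one YAML file, per-module blocks, one global
seed) determines every artifact; identical config + seed reproduces results
byte-for-byte.  Each stage appends an audit entry recording the parameters
actually used and the point counts in and out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidParameterError
from .features import clean_records, feature_set, normalize_rows
from .filtering import (
    PassThroughBounds,
    RadiusFilterParams,
    RansacPlaneParams,
    pass_through,
    radius_outlier_removal,
    remove_floor,
)
from .geometry import merge_views
from .io import read_herd_csv, write_json, write_ply, write_transforms_json
from .mlp import SplitSpec, WeightMLPRegressor, evaluate, split_dataset
from .morphometry import MorphometryConfig, measure_pig
from .registration import estimate_cube_registration
from .synthetic import (
    SceneSpec,
    compose_scene,
    cylinder_pig,
    default_rig,
    generate_herd_records,
    generate_pig_cloud,
    render_views,
    standard_pig,
)

__all__ = ["RunConfig", "run_measurement_pipeline", "run_weight_pipeline"]


@dataclass
class RunConfig:
    """Per-module parameter blocks with one global seed."""

    seed: int = 0
    out_dir: str | None = None
    pig: dict = field(default_factory=dict)           # kind + shape overrides
    scene: dict = field(default_factory=dict)         # SceneSpec overrides
    registration: dict = field(default_factory=dict)  # n_cube_points, cube_noise_sd
    filtering: dict = field(default_factory=dict)     # enabled, bounds, ransac, radius
    morphometry: dict = field(default_factory=dict)   # MorphometryConfig overrides
    herd: dict = field(default_factory=dict)          # csv path or generator block
    training: dict = field(default_factory=dict)      # epochs, normalized, model_ids

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _build_pig(cfg: dict):
    kind = cfg.get("kind", "standard")
    kwargs = {k: v for k, v in cfg.items() if k != "kind"}
    if kind == "standard":
        return standard_pig(**kwargs)
    if kind == "cylinder":
        return cylinder_pig(**kwargs)
    raise InvalidParameterError(f"unknown pig kind {kind!r}")


def run_measurement_pipeline(config: RunConfig) -> dict:
    """Synthetic scene → register → filter → measure, with an audit log.

    Returns a JSON-serializable dict holding the measurements, the
    generator ground truth, the recovered view transforms and the audit
    trail.  When ``config.out_dir`` is set, clouds (PLY), transforms (JSON)
    and the result JSON are written there.
    """
    audit: list[dict] = []
    seed = int(config.seed)

    pig = _build_pig(config.pig)
    scene_kwargs = dict(config.scene)
    n_pig = int(scene_kwargs.pop("n_pig_points", 20_000))
    cloud_noise = float(scene_kwargs.pop("noise_sd", 0.002))
    pig_cloud, truth = generate_pig_cloud(pig, n_pig, cloud_noise, seed)
    spec = SceneSpec(
        pig=pig, n_pig_points=n_pig, noise_sd=cloud_noise, seed=seed, **scene_kwargs
    )
    scene, labels = compose_scene(pig_cloud, spec)
    audit.append(
        {"stage": "simulate", "seed": seed, "n_pig": n_pig,
         "noise_sd": cloud_noise, "n_scene": len(scene)}
    )

    rig = default_rig()
    reg_cfg = dict(config.registration)
    use_registration = reg_cfg.pop("enabled", True)
    if use_registration:
        n_cube = int(reg_cfg.pop("n_cube_points", 3000))
        cube_noise = float(reg_cfg.pop("cube_noise_sd", 0.0))
        views, cube_views = render_views(scene, rig, n_cube, cube_noise, seed)
        transforms = estimate_cube_registration(
            cube_views, rig.cube_size, rig.cube_pose, **reg_cfg
        )
        merged = merge_views(views, transforms)
        audit.append(
            {"stage": "register", "n_cube_points": n_cube,
             "cube_noise_sd": cube_noise, "n_merged": len(merged)}
        )
    else:
        merged = scene
        transforms = []
        audit.append({"stage": "register", "skipped": True})

    filt = dict(config.filtering)
    if filt.pop("enabled", True):
        bounds_cfg = filt.get("bounds")
        if bounds_cfg is None:
            bounds = PassThroughBounds(y=(-0.26, 0.26), z=(-0.05, 1.5))
        else:
            bounds = PassThroughBounds(
                **{k: tuple(v) for k, v in bounds_cfg.items() if v is not None}
            )
        cropped = pass_through(merged, bounds)
        ransac = RansacPlaneParams(seed=seed, **filt.get("ransac", {}))
        no_floor, floor_plane = remove_floor(cropped, ransac)
        radius = RadiusFilterParams(**filt.get("radius", {}))
        pig_only = radius_outlier_removal(no_floor, radius)
        audit.append(
            {"stage": "filter", "n_cropped": len(cropped),
             "n_after_floor": len(no_floor), "n_pig": len(pig_only),
             "ransac_threshold": ransac.distance_threshold,
             "radius": radius.radius, "min_neighbors": radius.min_neighbors}
        )
    else:
        pig_only, floor_plane = merged, None
        audit.append({"stage": "filter", "skipped": True})

    morph_cfg = MorphometryConfig(**config.morphometry)
    result = measure_pig(pig_only, floor=floor_plane, config=morph_cfg)
    audit.append({"stage": "measure", "n_points": len(pig_only)})

    out = {
        "measurements": result.to_dict(),
        "ground_truth": truth.to_dict(),
        "transforms": [t.to_dict() for t in transforms],
        "audit": audit,
        "seed": seed,
    }
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_ply(out_dir / "scene.ply", scene, labels)
        write_ply(out_dir / "pig_filtered.ply", pig_only)
        if transforms:
            write_transforms_json(out_dir / "transforms.json", transforms)
        write_json(out_dir / "measurements.json", out)
    return out


def run_weight_pipeline(config: RunConfig) -> dict:
    """Herd table → clean → (normalize) → split → train 4 models → metrics.

    Returns per-model MSE/RMSE/MAE/MAPE on the test split (Table-shaped
    report), plus the split sizes.
    """
    seed = int(config.seed)
    herd_cfg = dict(config.herd)
    csv_path = herd_cfg.pop("csv", None)
    if csv_path:
        records = read_herd_csv(csv_path)
    else:
        records = generate_herd_records(
            n=int(herd_cfg.pop("n", 10_000)), seed=seed, **herd_cfg
        )
    table = clean_records(records)

    train_cfg = dict(config.training)
    normalized = bool(train_cfg.pop("normalized", True))
    model_ids = list(train_cfg.pop("model_ids", (1, 2, 3, 4)))
    epochs = int(train_cfg.pop("epochs", 300))
    if normalized:
        table = normalize_rows(table)

    train, test, validation = split_dataset(table, SplitSpec(seed=seed))
    report: dict = {
        "normalized": normalized,
        "n_train": len(train), "n_test": len(test), "n_validation": len(validation),
        "models": {},
    }
    for model_id in model_ids:
        cols = feature_set(model_id)
        model = WeightMLPRegressor(
            epochs=epochs, random_state=seed + model_id, **train_cfg
        )
        model.fit(
            train[cols].to_numpy(), train["Weight"].to_numpy(),
            validation_data=(
                validation[cols].to_numpy(), validation["Weight"].to_numpy()
            ) if len(validation) else None,
        )
        rep = evaluate(test["Weight"].to_numpy(), model.predict(test[cols].to_numpy()))
        report["models"][f"model_{model_id}"] = rep.to_dict()

    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_json(out_dir / "weight_metrics.json", report)
    return report
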