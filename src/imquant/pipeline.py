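"""Configuration-driven orchestration of the analysis stages.

A run is a YAML/dict configuration listing stages executed in order; each
stage reads named artifacts produced by earlier stages (or files) and
publishes its own under ``<stage_name>.<output>``. One global seed fans
out deterministically to per-stage seeds, and the returned manifest echoes
every stage's parameters, seed and outputs, which is sufficient to
reproduce the run.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import delineation, domain_quant, modeling, phantoms, registration
from .grid import ImageVolume, LabelMask, read_volume, write_volume
from .radiomics import ExtractionSettings, build_registry, extract_all

logger = logging.getLogger(__name__)

__all__ = ["StageConfig", "RunConfig", "run_pipeline", "load_config"]

STAGE_KINDS = ("phantom", "delineate", "roi", "radiomics", "register",
               "model", "quant")


class StageConfig(BaseModel):
    name: str
    kind: Literal["phantom", "delineate", "roi", "radiomics", "register",
                  "model", "quant"]
    params: dict[str, Any] = Field(default_factory=dict)


class RunConfig(BaseModel):
    stages: list[StageConfig]
    seed: int = 0
    output_dir: str = "runs/out"
    log_level: str = "INFO"

    @field_validator("stages")
    @classmethod
    def _unique_names(cls, v):
        names = [s.name for s in v]
        if len(set(names)) != len(names):
            raise ValueError("stage names must be unique")
        return v


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.model_validate(yaml.safe_load(fh))


def _stage_seed(global_seed: int, index: int) -> int:
    # documented fan-out: one global seed -> distinct per-stage seeds
    return int((global_seed * 1_000_003 + 7919 * index + 1) % (2**31 - 1))


def _resolve(context: dict, ref: Any) -> Any:
    """A string starting with '@' references an earlier stage output."""
    if isinstance(ref, str) and ref.startswith("@"):
        key = ref[1:]
        if key not in context:
            raise KeyError(f"unknown artifact reference {ref!r}; "
                           f"available: {sorted(context)}")
        return context[key]
    return ref


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the run manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    context: dict[str, Any] = {}
    manifest: dict[str, Any] = {"seed": config.seed, "stages": [], "outputs": {}}
    for i, stage in enumerate(config.stages):
        seed = _stage_seed(config.seed, i)
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_HANDLERS[stage.kind](stage, seed, context, out_dir)
        except Exception as exc:
            manifest["error"] = {"stage": stage.name, "message": str(exc)}
            _write_manifest(manifest, out_dir)
            raise
        for k, v in outputs.items():
            context[f"{stage.name}.{k}"] = v
        manifest["stages"].append({
            "name": stage.name, "kind": stage.kind, "seed": seed,
            "params": stage.params, "outputs": sorted(outputs),
            "elapsed_s": round(time.perf_counter() - t0, 3),
        })
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Stage handlers
# ---------------------------------------------------------------------------

def _stage_phantom(stage: StageConfig, seed: int, context, out_dir) -> dict:
    p = dict(stage.params)
    kind = p.pop("kind", "sphere")
    p.setdefault("seed", seed)
    if kind == "feature_dataset":
        table, truth = phantoms.make_feature_dataset(**p)
        path = out_dir / f"{stage.name}_table.csv"
        table.to_csv(path, index=False)
        return {"table": table, "truth": truth, "path": str(path)}
    if kind == "lung":
        ct, labels, lesion, truth = phantoms.make_lung_phantom(**p)
        return {"ct": ct, "lungs": labels, "lesion": lesion, "truth": truth}
    if kind == "knee":
        p.pop("seed")
        masks, truth = phantoms.make_knee_phantom(**p)
        return {**masks, "truth": truth}
    if kind == "brain":
        mask, table, truth = phantoms.make_brain_phantom(**p)
        return {"mask": mask, "normative_table": table, "truth": truth}
    spec = phantoms.PhantomSpec(kind=kind, **{k: tuple(v) if isinstance(v, list) else v
                                              for k, v in p.items()})
    vol, mask, truth = phantoms.make_geometric_phantom(spec)
    write_volume(vol, out_dir / f"{stage.name}_image.nii.gz")
    write_volume(mask, out_dir / f"{stage.name}_mask.nii.gz")
    return {"image": vol, "mask": mask, "truth": truth}


def _load_ref(context, value, as_mask=False):
    obj = _resolve(context, value)
    if isinstance(obj, (ImageVolume, LabelMask)):
        return obj
    return read_volume(obj, as_mask=as_mask)


def _stage_radiomics(stage: StageConfig, seed: int, context, out_dir) -> dict:
    p = stage.params
    image = _load_ref(context, p["image"])
    mask = _load_ref(context, p["mask"], as_mask=True)
    registry = build_registry(enable_filters=bool(p.get("enable_filters", True)))
    settings = ExtractionSettings()
    fv = extract_all(image, mask, registry, settings, seed=p.get("seed", seed))
    path = out_dir / f"{stage.name}_features.csv"
    fv.to_series().to_frame("value").rename_axis("feature").to_csv(path)
    return {"features": fv, "path": str(path)}


def _stage_roi(stage: StageConfig, seed: int, context, out_dir) -> dict:
    p = stage.params
    op = p["op"]
    if op == "morph":
        mask = _load_ref(context, p["mask"], as_mask=True)
        out = delineation.morph_modify(mask, p["mode"], p["distances_mm"])
    elif op == "bool":
        masks = [_load_ref(context, m, as_mask=True) for m in p["masks"]]
        out = delineation.roi_boolean(masks, p["operation"])
    elif op == "separate":
        mask = _load_ref(context, p["mask"], as_mask=True)
        vol = _load_ref(context, p["volume"]) if "volume" in p else None
        out = delineation.roi_separate(mask, vol, p.get("by", "connectivity"),
                                       intervals=p.get("intervals"),
                                       connectivity=p.get("connectivity", 26),
                                       min_size=p.get("min_size", 1))
    elif op == "duplicate":
        mask = _load_ref(context, p["mask"], as_mask=True)
        target = _load_ref(context, p["target"])
        out = delineation.roi_duplicate(mask, target)
    else:
        raise ValueError(f"unknown roi op {op!r}")
    write_volume(out, out_dir / f"{stage.name}_mask.nii.gz")
    return {"mask": out}


def _stage_delineate(stage: StageConfig, seed: int, context, out_dir) -> dict:
    p = stage.params
    volume = _load_ref(context, p["image"])
    rect = delineation.Rectangle2D(p["slice_index"], tuple(p["corner_min"]),
                                   tuple(p["corner_max"]))
    sl = volume.data[p["slice_index"]]
    mask2d, seeds = delineation.init_interactive(sl, rect)
    out = {"mask_slice": mask2d,
           "seeds": [{"position": list(s.position), "polarity": s.polarity}
                     for s in seeds]}
    if p.get("propagate", False):
        spec = delineation.PropagationSpec(**p.get("propagation", {}))
        out["mask"] = delineation.propagate_annotation(volume, mask2d,
                                                       p["slice_index"], spec)
        write_volume(out["mask"], out_dir / f"{stage.name}_mask.nii.gz")
    return out


def _stage_register(stage: StageConfig, seed: int, context, out_dir) -> dict:
    p = stage.params
    fixed = _load_ref(context, p["fixed"])
    moving = _load_ref(context, p["moving"])
    spec = registration.SimilaritySpec(p.get("metric", "MSD"))
    tf = registration.register_linear(fixed, moving, p.get("kind", "rigid"),
                                      spec, p.get("levels", 3), seed)
    tf.save(out_dir / f"{stage.name}_transform.txt")
    warped = registration.apply_transform(moving, tf, fixed)
    return {"transform": tf, "warped": warped}


def _stage_model(stage: StageConfig, seed: int, context, out_dir) -> dict:
    p = stage.params
    table = _resolve(context, p["table"])
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    split = modeling.split_data(table, modeling.SplitSpec(
        "random_proportion", p.get("train_fraction", 0.7), seed=p.get("seed", seed)))
    train = table[(split == "train").to_numpy()]
    test = table[(split == "test").to_numpy()]
    train_s, test_s, _ = modeling.standardize(
        train, test, modeling.ScalerSpec(p.get("scaler", "zscore")))
    sel = modeling.select_features(train_s, p.get("selector", "lasso"),
                                   k=p.get("k", 10), seed=p.get("seed", seed))
    if sel.selected is not None and not sel.selected:
        raise ValueError("feature selection kept no features")
    train_f, test_f = sel.transform(train_s), sel.transform(test_s)
    clf = modeling.fit_classifier(train_f, modeling.ClassifierSpec(
        p.get("algorithm", "logistic_regression"),
        p.get("hyperparameters", {}), p.get("seed", seed)))
    scores = clf.predict_proba(test_f[modeling.feature_columns(test_f)].to_numpy())[:, 1]
    report = modeling.evaluate_classifier(scores, test_f["label"].to_numpy())
    path = out_dir / f"{stage.name}_report.json"
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=str)
    return {"report": report, "selected": sel.selected, "path": str(path)}


def _stage_quant(stage: StageConfig, seed: int, context, out_dir) -> dict:
    p = stage.params
    target = p["target"]
    if target == "knee":
        rep = domain_quant.knee_metrics(
            _load_ref(context, p["bones"], as_mask=True),
            _load_ref(context, p["cartilages"], as_mask=True),
            _load_ref(context, p["menisci"], as_mask=True),
            knee_side=p.get("knee_side", "right"))
        payload = rep.__dict__
    elif target == "lung":
        rep = domain_quant.pneumonia_features(
            _load_ref(context, p["ct"]), _resolve(context, p["lungs"]),
            _load_ref(context, p["lesion"], as_mask=True))
        payload = rep.as_vector().to_dict()
    elif target == "brain":
        mask = _load_ref(context, p["mask"], as_mask=True)
        table = _resolve(context, p["normative_table"])
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table)
        rep = domain_quant.brain_report(mask, table, p.get("sex", "any"),
                                        p.get("age", 60),
                                        phantoms.brain_pairing())
        payload = {"volumes": rep.volumes, "asymmetry": rep.asymmetry,
                   "flags": rep.flags}
    else:
        raise ValueError(f"unknown quant target {target!r}")
    path = out_dir / f"{stage.name}_report.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return {"report": rep, "path": str(path)}


_STAGE_HANDLERS = {
    "phantom": _stage_phantom,
    "radiomics": _stage_radiomics,
    "roi": _stage_roi,
    "delineate": _stage_delineate,
    "register": _stage_register,
    "model": _stage_model,
    "quant": _stage_quant,
}
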