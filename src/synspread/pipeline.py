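"""Pipeline orchestration: config, staged execution, reproducible outputs.

``run_pipeline`` executes segment → measure → calibrate → classify →
summarise for one mode and writes a result bundle:

- ``records.csv``   — classified per-cell records (one row per cell, with
  a ``field`` column naming the source image);
- ``thresholds.json`` — calibrated thresholds with provenance;
- ``metrics.json``  — the mode's summary quantities;
- ``run_log.json``  — seed, package version, mode and a SHA-256 hash of
  the resolved configuration, sufficient to reproduce the run.

Outputs are deterministic: identical config + seed give byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .gating import (
    GatingScheme,
    MODE_IN_VITRO,
    MODE_IN_VIVO,
    PunctaParams,
    annexin_imaging_index,
    classify_in_vitro,
    classify_in_vivo,
    detect_puncta,
)
from .image_io import import_label_mask, read_image, read_region_mask
from .intensity import (
    RULE_MEAN_K_SD,
    RULE_PERCENTILE,
    ThresholdSet,
    calibrate_threshold,
    measure_cell_intensities,
    sample_control_patches,
)
from .metrics import (
    aggregate_region_counts,
    compute_spread_metrics,
    count_recipients_by_region,
)
from .morphometry import MorphometryParams, measure_neurites
from .segment import SegmentationParams, segment_somata

MODE_PUNCTA = "PUNCTA"
MODE_ANNEXIN = "ANNEXIN"
MODE_MORPHOMETRY = "MORPHOMETRY"
MODES = (MODE_IN_VITRO, MODE_IN_VIVO, MODE_PUNCTA, MODE_ANNEXIN, MODE_MORPHOMETRY)

#: Logical channel roles each mode must be able to resolve.
_REQUIRED_ROLES = {
    MODE_IN_VITRO: ("morphology", "egfp", "ha"),
    MODE_IN_VIVO: ("mcherry", "egfp", "ha"),
    MODE_PUNCTA: ("morphology", "ha"),
    MODE_ANNEXIN: ("morphology", "fitc"),
    MODE_MORPHOMETRY: ("morphology",),
}


class PipelineValidationError(ValueError):
    """Configuration problem detected before any computation."""


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and file context."""


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    images: list[str]
    out_dir: str
    mode: str = MODE_IN_VITRO
    condition: str = ""
    seed: int = 0
    channel_map: dict = field(default_factory=lambda: {
        "morphology": "NFH", "egfp": "eGFP", "ha": "HA",
        "mcherry": "mCherry", "fitc": "FITC",
    })
    control_images: list[str] = field(default_factory=list)
    region_masks: list[str] = field(default_factory=list)
    label_masks: list[str] = field(default_factory=list)
    segmentation: dict = field(default_factory=dict)
    puncta: dict = field(default_factory=dict)
    morphometry: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=lambda: {
        "egfp_rule": RULE_PERCENTILE, "egfp_param": 99.0,
        "mcherry_rule": RULE_PERCENTILE, "mcherry_param": 99.0,
        "ha_rule": RULE_MEAN_K_SD, "ha_param": 3.0,
        "section_patch_radius": 8.0, "section_n_patches": 200,
    })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise PipelineValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        defaults = cls(images=[], out_dir="")
        for key in ("channel_map", "thresholds"):
            merged = dict(getattr(defaults, key))
            merged.update(getattr(cfg, key))
            setattr(cfg, key, merged)
        return cfg

    def validate(self, mode: str | None = None) -> None:
        mode = mode or self.mode
        if mode not in MODES:
            raise PipelineValidationError(f"unknown mode {mode!r}; choose from {MODES}")
        if not self.images:
            raise PipelineValidationError("no input images configured")
        for role in _REQUIRED_ROLES[mode]:
            if role not in self.channel_map or not self.channel_map[role]:
                raise PipelineValidationError(
                    f"mode {mode} requires a channel mapping for {role!r}"
                )
        for path in [*self.images, *self.control_images,
                     *self.region_masks, *self.label_masks]:
            if not Path(path).exists():
                raise PipelineValidationError(f"input file does not exist: {path}")
        if mode in (MODE_IN_VITRO, MODE_IN_VIVO) and not self.control_images:
            raise PipelineValidationError(
                f"mode {mode} needs control_images for threshold calibration"
            )
        if mode == MODE_IN_VIVO and len(self.region_masks) != len(self.images):
            raise PipelineValidationError(
                "mode IN_VIVO needs one region mask per image"
            )
        if self.label_masks and len(self.label_masks) != len(self.images):
            raise PipelineValidationError(
                "label_masks, when given, must parallel images"
            )

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # incidental to the analysis itself
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def _stage(name: str, context: str = ""):
    """Decorator-free stage wrapper: re-raise with stage + file context."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(
                    f"stage {name!r} failed" + (f" for {context}" if context else "")
                    + f": {exc}"
                ) from exc
            return False
    return _Ctx()


def _segment(cfg: PipelineConfig, image, index: int, channel: str):
    if cfg.label_masks:
        labels = import_label_mask(cfg.label_masks[index])
        if labels.labels.shape != image.shape:
            raise PipelineValidationError(
                f"label mask {cfg.label_masks[index]} shape {labels.labels.shape} "
                f"does not match image shape {image.shape}"
            )
        return labels
    return segment_somata(image, channel, SegmentationParams(**cfg.segmentation))


def _calibrate_in_vitro(cfg: PipelineConfig) -> ThresholdSet:
    ch = cfg.channel_map
    frames = []
    for path in cfg.control_images:
        img = read_image(path)
        labels = segment_somata(
            img, ch["morphology"], SegmentationParams(**cfg.segmentation)
        )
        frames.append(measure_cell_intensities(img, labels))
    records = pd.concat(frames, ignore_index=True)
    t = cfg.thresholds
    ts = ThresholdSet()
    ts.add(calibrate_threshold(
        records[f"net_mean_{ch['egfp']}"], t["egfp_rule"], t["egfp_param"],
        channel=ch["egfp"], control_description="non-transduced culture",
    ))
    ts.add(calibrate_threshold(
        records[f"net_mean_{ch['ha']}"], t["ha_rule"], t["ha_param"],
        channel=ch["ha"], control_description="secondary-antibody-only control",
    ))
    return ts


def _calibrate_in_vivo(cfg: PipelineConfig) -> ThresholdSet:
    ch = cfg.channel_map
    t = cfg.thresholds
    control = read_image(cfg.control_images[0])
    patches = sample_control_patches(
        control, [ch["mcherry"], ch["egfp"], ch["ha"]],
        n_patches=int(t["section_n_patches"]),
        radius=float(t["section_patch_radius"]),
        seed=cfg.seed,
    )
    ts = ThresholdSet()
    for role, rule_key, param_key in (
        ("mcherry", "mcherry_rule", "mcherry_param"),
        ("egfp", "egfp_rule", "egfp_param"),
        ("ha", "ha_rule", "ha_param"),
    ):
        ts.add(calibrate_threshold(
            patches[f"net_mean_{ch[role]}"], t[rule_key], t[param_key],
            channel=ch[role],
            control_description="control-injected section patches",
        ))
    return ts


def run_pipeline(config: PipelineConfig, mode: str | None = None) -> dict:
    """Execute one mode end-to-end and write the result bundle.

    Returns the metrics dictionary that was written to ``metrics.json``.
    """
    mode = mode or config.mode
    config.validate(mode)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ch = config.channel_map
    scheme = GatingScheme(
        mode=mode if mode in (MODE_IN_VITRO, MODE_IN_VIVO) else MODE_IN_VITRO,
        egfp_channel=ch.get("egfp", "eGFP"),
        ha_channel=ch.get("ha", "HA"),
        mcherry_channel=ch.get("mcherry", "mCherry"),
    )

    thresholds = ThresholdSet()
    if mode == MODE_IN_VITRO:
        with _stage("calibrate"):
            thresholds = _calibrate_in_vitro(config)
    elif mode == MODE_IN_VIVO:
        with _stage("calibrate"):
            thresholds = _calibrate_in_vivo(config)

    all_records = []
    metrics: dict = {"mode": mode, "condition": config.condition, "fields": []}
    per_section_counts = []
    seg_channel = ch["mcherry"] if mode == MODE_IN_VIVO else ch["morphology"]

    for i, path in enumerate(config.images):
        with _stage("read", path):
            image = read_image(path)
        with _stage("segment", path):
            labels = _segment(config, image, i, seg_channel)
        with _stage("measure", path):
            records = measure_cell_intensities(image, labels)
        field_metrics: dict = {"image": Path(path).name, "n_cells": int(len(records))}

        if mode == MODE_IN_VITRO:
            with _stage("classify", path):
                records = classify_in_vitro(records, thresholds, scheme)
                m = compute_spread_metrics(records, condition=config.condition)
            field_metrics.update(m.to_dict())
        elif mode == MODE_IN_VIVO:
            with _stage("classify", path):
                records = classify_in_vivo(records, thresholds, scheme)
                mask = read_region_mask(config.region_masks[i])
                counts = count_recipients_by_region(records, mask)
            per_section_counts.append(counts)
            field_metrics.update(counts)
        elif mode == MODE_PUNCTA:
            with _stage("puncta", path):
                records, pct = detect_puncta(
                    image, ch["ha"], labels, records, PunctaParams(**config.puncta)
                )
            field_metrics["percent_aggregate_positive"] = pct
        elif mode == MODE_ANNEXIN:
            with _stage("annexin", path):
                field_metrics["annexin_index"] = annexin_imaging_index(
                    image, ch["fitc"], ch["morphology"], labels
                )
        elif mode == MODE_MORPHOMETRY:
            with _stage("morphometry", path):
                morph = measure_neurites(
                    image, ch["morphology"], labels,
                    MorphometryParams(**config.morphometry),
                )
            morph.insert(0, "field", Path(path).name)
            morph.to_csv(out / "morphometry.csv", index=False, mode="a" if i else "w",
                         header=not i)
            field_metrics["n_neurons"] = int(len(morph))
            field_metrics["mean_total_tree_length"] = (
                float(morph["total_tree_length"].mean()) if len(morph) else 0.0
            )

        records.insert(0, "field", Path(path).name)
        all_records.append(records)
        metrics["fields"].append(field_metrics)

    if mode == MODE_IN_VIVO and per_section_counts:
        metrics["animal_totals"] = aggregate_region_counts(per_section_counts)

    combined = pd.concat(all_records, ignore_index=True)
    combined.to_csv(out / "records.csv", index=False)
    if thresholds.entries:
        thresholds.to_json(out / "thresholds.json")
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True) + "\n")
    log = {
        "package_version": __version__,
        "mode": mode,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_images": len(config.images),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True) + "\n")
    return metrics
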