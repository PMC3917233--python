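"""End-to-end orchestration: from images (or synthetic specs) to tables.

A run is driven by a :class:`RunConfig` (round-trips through YAML), writes
all artifacts into a fixed run-directory layout::

    run_dir/
      images/    stitched + preprocessed images, masks
      labels/    segmentation label maps (16-bit TIFF)
      tables/    feature tables, classified tables, QC logs (CSV)
      models/    trained classifier directories
      reports/   phenoprints, morphodynamics and pole analyses (CSV)
      config.resolved.yaml
      run.log

and never mutates a previous stage's outputs.  Reruns with the same config
and seed reproduce deterministic stages bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import descriptors, imaging, qc, synthdata
from .classify import Classifier

log = logging.getLogger("quanthisto")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    # input: either a synthetic section spec or an image + masks on disk
    synthetic_seed: int | None = 0
    #: overrides for the synthetic SectionSpec (zone_radii, wall_width,
    #: noise, pole_arc_spacing, cell_size_params as plain dicts ...)
    synthetic_overrides: dict = field(default_factory=dict)
    image_path: str | None = None
    section_mask_path: str | None = None
    xylem_mask_path: str | None = None
    pixel_size: float = 0.35
    center: tuple[float, float] | None = None
    genotype: str = "synthetic"
    timepoint: str = "NA"
    # preprocessing / binarization / morphology / watershed
    gamma: float = 1.0
    contrast: float = 1.0
    brightness: float = 0.0
    window_px: int = 51
    offset: float = 10.0
    n_erosions: int = 2
    n_dilations: int = 1
    selem_radius: int = 1
    h_rel: float = 0.6
    h_min: float = 1.0
    min_cell_px: int = 20
    # classification / QC
    classifier_dir: str | None = None
    qc_bidirectional: bool = True
    # analysis defaults
    lowess_frac: float = 0.3
    dip_n_boot: int = 2000
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("center") is not None:
            data["center"] = tuple(data["center"])
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, run_dir) -> Path:
    """Execute segment -> features -> classify -> qc, writing a run directory.

    Synthetic runs (``synthetic_seed`` set) generate the input section and
    use its ground truth to train a classifier when none is given.  Any
    stage failure raises :class:`StageError` naming the stage; artifacts
    written so far are retained.
    """
    run_dir = Path(run_dir)
    for sub in ("images", "labels", "tables", "models", "reports"):
        (run_dir / sub).mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.resolved.yaml")
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    try:
        log.info("run start config=%s seed=%s", config.digest(), config.seed)

        # -- stage: input ---------------------------------------------------
        stage = "input"
        truth = None
        if config.synthetic_seed is not None:
            overrides = dict(config.synthetic_overrides)
            if "cell_size_params" in overrides:
                overrides["cell_size_params"] = {
                    k: synthdata.ZoneParams(**v) if isinstance(v, dict) else v
                    for k, v in overrides["cell_size_params"].items()}
            spec = synthdata.SectionSpec(seed=config.synthetic_seed,
                                         pixel_size=config.pixel_size,
                                         **overrides)
            image, truth, masks_arrays = synthdata.generate_section(spec)
            mask_pair = qc.MaskPair(masks_arrays["section"],
                                    masks_arrays["xylem"],
                                    provenance="synthetic")
        elif config.image_path:
            px = tifffile.imread(config.image_path)
            image = imaging.SectionImage(px, pixel_size=config.pixel_size,
                                         center=config.center)
            if not (config.section_mask_path and config.xylem_mask_path):
                raise StageError(stage, "mask paths required for image input")
            mask_pair = qc.MaskPair(
                tifffile.imread(config.section_mask_path) > 0,
                tifffile.imread(config.xylem_mask_path) > 0)
        else:
            raise StageError(stage, "no input: set synthetic_seed or image_path")
        tifffile.imwrite(run_dir / "images" / "section.tif", image.pixels)
        _log_stage(run_dir, "input", ["images/section.tif"])

        # -- stage: segment -------------------------------------------------
        stage = "segment"
        labels = imaging.segment_section(
            image, gamma=config.gamma, contrast=config.contrast,
            brightness=config.brightness, window_px=config.window_px,
            offset=config.offset, n_erosions=config.n_erosions,
            n_dilations=config.n_dilations, selem_radius=config.selem_radius,
            h_rel=config.h_rel, h_min=config.h_min,
            min_cell_px=config.min_cell_px)
        tifffile.imwrite(run_dir / "labels" / "labels.tif",
                         labels.labels.astype(np.uint16 if labels.labels.max()
                                              < 2 ** 16 else np.int32))
        _log_stage(run_dir, "segment", ["labels/labels.tif"])

        # -- stage: features ------------------------------------------------
        stage = "features"
        center = image.center if image.center is not None else config.center
        if center is None:
            raise StageError(stage, "section center is required")
        table = descriptors.build_feature_table(labels, center)
        descriptors.write_feature_table(table, run_dir / "tables" / "features.csv")
        _log_stage(run_dir, "features", ["tables/features.csv"])

        # -- stage: classify ------------------------------------------------
        stage = "classify"
        if config.classifier_dir:
            clf = Classifier.load(config.classifier_dir)
        elif truth is not None:
            labeled = _labeled_from_truth(labels, table, truth)
            from .classify import (greedy_feature_selection, split_training,
                                   tune_hyperparameters)
            ts = split_training(labeled, seed=config.seed)
            _, (feats, _, _) = greedy_feature_selection(
                ts.learn, V=5, seed=config.seed, max_k=6)
            C, gamma, _, _ = tune_hyperparameters(ts.learn, list(feats),
                                                  seed=config.seed)
            clf = Classifier.train(ts.learn, list(feats), C, gamma,
                                   seed=config.seed,
                                   genotype=config.genotype,
                                   timepoint=config.timepoint)
            clf.save(run_dir / "models" /
                     f"{config.genotype}_{config.timepoint}")
        else:
            raise StageError(
                stage, f"no classifier for key "
                       f"({config.genotype}, {config.timepoint})")
        classified = table.copy()
        classified["class"] = clf.predict(table)
        classified.to_csv(run_dir / "tables" / "classified.csv", index=False)
        _log_stage(run_dir, "classify", ["tables/classified.csv"])

        # -- stage: qc ------------------------------------------------------
        stage = "qc"
        final, report = qc.run_qc(classified, mask_pair,
                                  bidirectional=config.qc_bidirectional)
        final.to_csv(run_dir / "tables" / "qc_passed.csv", index=False)
        report["change_log"].to_csv(run_dir / "tables" / "qc_changes.csv",
                                    index=False)
        _log_stage(run_dir, "qc",
                   ["tables/qc_passed.csv", "tables/qc_changes.csv"])

        meta = {"config": config.digest(), "seed": config.seed,
                "elapsed_s": round(time.time() - t0, 2),
                "n_cells": int(len(final))}
        (run_dir / "reports" / "run_meta.json").write_text(
            json.dumps(meta, indent=2))
        log.info("run complete in %.1fs", time.time() - t0)
        return run_dir
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(stage, str(exc)) from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _labeled_from_truth(labels, table: pd.DataFrame, truth) -> pd.DataFrame:
    """Attach ground-truth classes to feature rows by cell id."""
    out = table.copy()
    out["class"] = out["cell_id"].map(
        lambda i: truth.cell_classes[int(i)].value
        if int(i) in truth.cell_classes else None)
    return out.dropna(subset=["class", "incline"]).reset_index(drop=True)


def _log_stage(run_dir: Path, stage: str, outputs: list[str]) -> None:
    sums = {o: _sha256(run_dir / o) for o in outputs}
    log.info("stage=%s outputs=%s", stage, json.dumps(sums))
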