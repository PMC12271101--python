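"""End-to-end 5-fold cross-validation experiment orchestration.

Ties the stages together: simulate (or load) a slide manifest, patchify,
split into stratified slide-level folds, train one classifier per fold,
predict the held-out slides, and assemble the fold-by-fold metric report
with its average row.  A single global seed fans out deterministically to
the simulator, the fold split, and each fold's training run, so one
number reproduces the whole experiment byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .evaluation import MetricReport, average_metrics, evaluate_fold
from .inference import aggregate_majority, predict_patches, save_heatmap_png
from .patching import GridConfig, patchify_manifest, read_slide
from .preprocess import AugmentConfig, HsvThresholds
from .synthetic import CollagenColorModel, SceneSpec, build_dataset
from .training import (
    FoldSplit,
    LabelScheme,
    TrainConfig,
    stratified_folds,
    train_model,
)

log = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one cross-validation experiment."""

    mode: str = "seven_class"
    k: int = 5
    seed: int = 0
    out_dir: str = "fibrostage_run"
    #: None = load `manifest` instead of simulating
    wsi_per_class: int | None = 12
    manifest: str | None = None
    scene: SceneSpec = field(default_factory=SceneSpec)
    grid: GridConfig = field(default_factory=GridConfig)
    thresholds: HsvThresholds = field(default_factory=HsvThresholds)
    #: geometric-only augmentation by default: synthetic stain colors are
    #: deterministic, so color jitter would only erase the class signal
    augment: AugmentConfig = field(default_factory=lambda: AugmentConfig(color=False))
    train: TrainConfig = field(default_factory=TrainConfig)
    heatmaps: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("cross-validation requires k >= 2")
        LabelScheme(self.mode)  # validates

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, klass in (
            ("scene", SceneSpec), ("grid", GridConfig),
            ("thresholds", HsvThresholds), ("augment", AugmentConfig),
            ("train", TrainConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = kwargs[key]
                if key == "scene" and isinstance(sub.get("stain_model"), dict):
                    sm = sub["stain_model"]
                    for f in ("collagen_hsv_center", "parenchyma_hsv_center",
                              "hsv_jitter_sd", "background_rgb"):
                        if f in sm:
                            sm[f] = tuple(sm[f])
                    sub["stain_model"] = CollagenColorModel(**sm)
                kwargs[key] = klass(**sub)
        return cls(**kwargs)


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


def _fanout_seeds(seed: int) -> dict[str, int]:
    """Derive stage seeds (simulate/split/train) from the global seed."""
    rng = np.random.default_rng(np.random.SeedSequence([1009, seed & 0x7FFFFFFF]))
    return {
        "simulate": int(rng.integers(0, 2**31)),
        "split": int(rng.integers(0, 2**31)),
        "train": int(rng.integers(0, 2**31)),
    }


def run_crossval(config: ExperimentConfig, resume: bool = False):
    """Run the full k-fold experiment; returns (MetricReport, report path).

    Every output file is stamped with the config hash and seed.  With
    ``resume=True``, folds whose metric files already exist are reused.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _fanout_seeds(config.seed)
    scheme = LabelScheme(config.mode)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    if config.manifest is not None:
        manifest = pd.read_csv(config.manifest, dtype={"score": str})
        log.info("loaded manifest with %d slides", len(manifest))
    else:
        if config.wsi_per_class is None:
            raise ValueError("need either a manifest or simulator counts")
        counts = {s: config.wsi_per_class for s in reference.SCORES_7}
        manifest = build_dataset(
            counts, config.scene, out / "slides", seed=seeds["simulate"]
        )
        log.info("simulated %d slides", len(manifest))

    per_slide, patch_manifest = patchify_manifest(manifest, config.grid)
    patch_manifest.to_csv(out / "patches.csv", index=False)
    scores = dict(zip(manifest["wsi_id"], manifest["score"]))

    split = stratified_folds(manifest, k=config.k, seed=seeds["split"])
    (out / "folds.json").write_text(
        json.dumps({**stamp, **split.to_json_dict()}, indent=1)
    )

    fold_rows = []
    for fold in range(config.k):
        metrics_path = out / f"fold{fold}_metrics.json"
        if resume and metrics_path.exists():
            fold_rows.append(json.loads(metrics_path.read_text())["metrics"])
            log.info("fold %d: resumed from %s", fold, metrics_path)
            continue
        row = _run_fold(
            fold, split, per_slide, scores, scheme, config, seeds, out,
            manifest,
        )
        metrics_path.write_text(json.dumps({**stamp, "metrics": row}, indent=1))
        fold_rows.append(row)

    report = average_metrics(fold_rows)
    table = report.to_frame()
    report_path = out / "report.csv"
    table.to_csv(report_path, index=False)
    (out / "run.json").write_text(json.dumps(stamp, indent=1))
    log.info("report written to %s", report_path)
    return report, report_path


def simulate_patch_sets(
    wsi_per_class: int,
    scene: SceneSpec,
    grid: GridConfig,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, list], dict[str, str]]:
    """Simulate slides and patchify them in memory (no files written)."""
    from .patching import patchify_slide
    from .synthetic import generate_scene

    rng = np.random.default_rng(np.random.SeedSequence([577, seed & 0x7FFFFFFF]))
    per_slide, scores, rows = {}, {}, []
    for score in reference.SCORES_7:
        for idx in range(wsi_per_class):
            spec = dataclasses.replace(scene, seed=int(rng.integers(0, 2**31)))
            img, _ = generate_scene(score, spec)
            wsi_id = f"s{score}_{idx:03d}"
            per_slide[wsi_id], _ = patchify_slide(
                img, wsi_id, spec.magnification, grid
            )
            scores[wsi_id] = score
            rows.append(
                {"wsi_id": wsi_id, "path": "", "magnification": spec.magnification,
                 "score": score}
            )
    return pd.DataFrame(rows), per_slide, scores


def single_fold_benchmark(
    config: ExperimentConfig, fold: int = 0
) -> tuple[dict[str, float], pd.DataFrame]:
    """Train and validate one stratified fold on simulated slides.

    The desk-scale counterpart of one cross-validation iteration: simulate
    ``wsi_per_class`` slides per stage (in memory), hold out one
    stratified fold, train up to the configured epoch budget with the
    early-stopping rule, and return the held-out fold's slide-level
    metric row together with the training history.
    """
    seeds = _fanout_seeds(config.seed)
    scheme = LabelScheme(config.mode)
    manifest, per_slide, scores = simulate_patch_sets(
        config.wsi_per_class, config.scene, config.grid, seeds["simulate"]
    )
    split = stratified_folds(manifest, k=config.k, seed=seeds["split"])
    train_ids = [w for w in split.train_ids(fold) if per_slide.get(w)]
    val_ids = [w for w in split.val_ids(fold) if per_slide.get(w)]
    fold_train = dataclasses.replace(
        config.train, seed=(seeds["train"] + fold) & 0x7FFFFFFF
    )
    model, history = train_model(
        {w: per_slide[w] for w in train_ids}, scores,
        {w: per_slide[w] for w in val_ids}, scores,
        scheme, fold_train,
        thresholds=config.thresholds,
        augment_config=config.augment if config.train.augment else None,
    )
    true_idx, pred_idx, ratios = [], [], []
    for w in val_ids:
        preds = predict_patches(model, per_slide[w], config.thresholds)
        wsi_pred = aggregate_majority(preds, scheme.num_classes)
        true_idx.append(scheme.index_of(scores[w]))
        pred_idx.append(wsi_pred.pred_index)
        ratios.append(wsi_pred.ratio_vector)
    row = evaluate_fold(
        np.asarray(true_idx), np.asarray(pred_idx), np.asarray(ratios),
        scheme.num_classes,
    )
    return row, history


def _run_fold(
    fold: int,
    split: FoldSplit,
    per_slide: dict,
    scores: dict[str, str],
    scheme: LabelScheme,
    config: ExperimentConfig,
    seeds: dict[str, int],
    out: Path,
    manifest: pd.DataFrame,
) -> dict[str, float]:
    train_ids = [w for w in split.train_ids(fold) if per_slide.get(w)]
    val_ids = [w for w in split.val_ids(fold) if per_slide.get(w)]
    log.info("fold %d: %d train / %d val slides", fold, len(train_ids), len(val_ids))

    fold_train = dataclasses.replace(
        config.train, seed=(seeds["train"] + fold) & 0x7FFFFFFF
    )
    model, history = train_model(
        {w: per_slide[w] for w in train_ids},
        scores,
        {w: per_slide[w] for w in val_ids},
        scores,
        scheme,
        fold_train,
        thresholds=config.thresholds,
        augment_config=config.augment if config.train.augment else None,
    )
    history.to_csv(out / f"fold{fold}_history.csv", index=False)
    model.save(out / f"fold{fold}_model.npz")
    (out / f"fold{fold}_model.json").write_text(
        json.dumps(
            {
                "mode": scheme.mode,
                "stopping_epoch": int(history["epoch"].iloc[-1]),
                "train_config": _as_jsonable(fold_train),
            },
            indent=1, default=str,
        )
    )

    true_idx, pred_idx, ratios, summary_rows = [], [], [], []
    pred_rows = []
    for w in val_ids:
        preds = predict_patches(model, per_slide[w], config.thresholds)
        wsi_pred = aggregate_majority(preds, scheme.num_classes)
        true_idx.append(scheme.index_of(scores[w]))
        pred_idx.append(wsi_pred.pred_index)
        ratios.append(wsi_pred.ratio_vector)
        summary_rows.append(
            {"wsi_id": w, "pred_score": scheme.class_names[wsi_pred.pred_index],
             **{f"r{c}": wsi_pred.ratio_vector[c]
                for c in range(scheme.num_classes)}}
        )
        for (r, c), cls, prob in zip(
            preds.grid_coords, preds.pred_class, preds.probabilities
        ):
            pred_rows.append(
                {"wsi_id": w, "row": int(r), "col": int(c),
                 "pred_class": scheme.class_names[int(cls)],
                 **{f"p{i}": float(prob[i]) for i in range(scheme.num_classes)}}
            )
        if config.heatmaps:
            rec = manifest.loc[manifest["wsi_id"] == w].iloc[0]
            slide = read_slide(rec.path)
            save_heatmap_png(
                out / f"fold{fold}_{w}_heatmap.png", preds, slide,
                config.grid.side_for(rec.magnification), scheme.class_names,
            )
    pd.DataFrame(pred_rows).to_csv(out / f"fold{fold}_predictions.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(out / f"fold{fold}_summaries.csv", index=False)
    return evaluate_fold(
        np.asarray(true_idx), np.asarray(pred_idx), np.asarray(ratios),
        scheme.num_classes,
    )
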