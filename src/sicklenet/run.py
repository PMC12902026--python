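"""Run-directory orchestration for the pipeline stages.

Each stage reads its inputs from the run directory, writes its outputs
there, and appends an entry (stage, config hash, seed, inputs, outputs,
wall time) to ``run_manifest.json``, so a run is reconstructible from its
manifest.  Completed stages are skipped on re-run unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from typing import Dict, List

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import classifiers, metrics
from .config import PipelineConfig
from .embedding_net import (
    BackboneSpec,
    EmbeddingModel,
    HeadSpec,
    build_model,
    embeddings_from_frame,
    embeddings_to_frame,
)
from .gradcam import gradcam, overlay
from .pipeline import extract_features
from .quality import FilterConfig, filter_dataset
from .synthetic import JitterParams, LabeledDataset, generate_dataset, read_dataset, write_dataset
from .trainer import TrainConfig, train

logger = logging.getLogger(__name__)

STAGES = ("generate", "filter", "train", "embed", "classify", "explain", "report")


class MissingArtifactError(FileNotFoundError):
    pass


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:12]


def _append_manifest(out_dir: str, entry: Dict) -> None:
    path = os.path.join(out_dir, "run_manifest.json")
    entries = []
    if os.path.exists(path):
        with open(path) as fh:
            entries = json.load(fh)
    entries.append(entry)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2)


def _require(out_dir: str, relpath: str, producer: str) -> str:
    path = os.path.join(out_dir, relpath)
    if not os.path.exists(path):
        raise MissingArtifactError(
            f"missing artifact {relpath!r} under {out_dir!r}; "
            f"run the '{producer}' stage first"
        )
    return path


_STAGE_OUTPUTS = {
    "generate": ["images/train/manifest.csv", "images/test/manifest.csv"],
    "filter": ["quality_train.csv", "quality_test.csv"],
    "train": ["checkpoint.npz", "history.csv"],
    "embed": ["embeddings_train.csv", "embeddings_test.csv"],
    "classify": ["predictions.csv"],
    "explain": ["heatmaps"],
    "report": ["results.csv"],
}


def stage_done(config: PipelineConfig, stage: str) -> bool:
    return all(
        os.path.exists(os.path.join(config.out_dir, p)) for p in _STAGE_OUTPUTS[stage]
    )


def _jitter(config: PipelineConfig) -> JitterParams:
    return JitterParams.separable() if config.generate.preset == "separable" else JitterParams()


def _filter_config(config: PipelineConfig) -> FilterConfig:
    f = config.filter
    return FilterConfig(
        w_b=f.w_b, w_z=f.w_z, n_train_per_class=f.n_train_per_class,
        n_test_per_class=f.n_test_per_class, blur_kernel=f.blur_kernel,
        threshold_mode=f.threshold_mode, fixed_threshold=f.fixed_threshold,
    )


def _load_filtered(config: PipelineConfig, split: str) -> LabeledDataset:
    quality = pd.read_csv(_require(config.out_dir, f"quality_{split}.csv", "filter"))
    img_dir = os.path.join(config.out_dir, "images", split)
    manifest = pd.read_csv(_require(config.out_dir, f"images/{split}/manifest.csv", "generate"))
    selected_ids = set(quality.loc[quality["selected"], "image_id"])
    keep = manifest[manifest["filename"].isin(selected_ids)]
    return read_dataset(img_dir, keep)


def run_stage(stage: str, config: PipelineConfig) -> List[str]:
    """Execute one stage; returns the relative paths it produced."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; stages: {STAGES}")
    os.makedirs(config.out_dir, exist_ok=True)
    t0 = time.time()
    outputs = _run_stage_impl(stage, config)
    _append_manifest(
        config.out_dir,
        {
            "stage": stage,
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "outputs": outputs,
            "wall_time_s": round(time.time() - t0, 3),
        },
    )
    logger.info("stage %s: wrote %d artifacts in %.1fs", stage, len(outputs), time.time() - t0)
    return outputs


def _run_stage_impl(stage: str, config: PipelineConfig) -> List[str]:
    out = config.out_dir
    if stage == "generate":
        jit = _jitter(config)
        size = (config.generate.image_size, config.generate.image_size)
        train_ds = generate_dataset(
            {"normal": config.generate.n_train_per_class,
             "sickle": config.generate.n_train_per_class},
            size=size, jitter=jit, seed=config.seed)
        test_ds = generate_dataset(
            {"normal": config.generate.n_test_per_class,
             "sickle": config.generate.n_test_per_class},
            size=size, jitter=jit, seed=config.seed + 10_000)
        write_dataset(train_ds, os.path.join(out, "images", "train"))
        write_dataset(test_ds, os.path.join(out, "images", "test"))
        return _STAGE_OUTPUTS["generate"]

    if stage == "filter":
        fcfg = _filter_config(config)
        for split, n in (("train", fcfg.n_train_per_class), ("test", fcfg.n_test_per_class)):
            img_dir = os.path.join(out, "images", split)
            manifest = pd.read_csv(
                _require(out, f"images/{split}/manifest.csv", "generate"))
            ds = read_dataset(img_dir, manifest)
            from .quality import rank_and_select, records_to_frame, score_batch

            records = score_batch(list(ds), list(manifest["filename"]),
                                  list(manifest["label"]), fcfg)
            rank_and_select(records, n, fcfg)
            records_to_frame(records).to_csv(
                os.path.join(out, f"quality_{split}.csv"), index=False)
        return _STAGE_OUTPUTS["filter"]

    if stage == "train":
        train_ds = _load_filtered(config, "train")
        head = "embedding" if config.model.loss == "triplet" else "probability"
        model = build_model(
            BackboneSpec(name=config.model.backbone, input_size=config.model.input_size),
            HeadSpec(mode=head), seed=config.seed)
        tcfg = TrainConfig(
            loss=config.model.loss, epochs=config.training.epochs,
            batch_size=config.training.batch_size, lr0=config.training.lr0,
            seed=config.seed, split_fraction=config.training.split_fraction,
            margin=config.training.margin, focal_alpha=config.training.focal_alpha,
            focal_gamma=config.training.focal_gamma)
        model, history = train(model, train_ds, tcfg)
        model.save(os.path.join(out, "checkpoint.npz"))
        history.to_frame().to_csv(os.path.join(out, "history.csv"), index=False)
        return _STAGE_OUTPUTS["train"]

    if stage == "embed":
        model = EmbeddingModel.load(_require(out, "checkpoint.npz", "train"))
        for split in ("train", "test"):
            ds = _load_filtered(config, split)
            quality = pd.read_csv(os.path.join(out, f"quality_{split}.csv"))
            ids = list(quality.loc[quality["selected"], "image_id"])
            batch = extract_features(model, list(ds), ds.labels(), source_ids=ids)
            embeddings_to_frame(batch).to_csv(
                os.path.join(out, f"embeddings_{split}.csv"), index=False)
        return _STAGE_OUTPUTS["embed"]

    if stage == "classify":
        train_b = embeddings_from_frame(
            pd.read_csv(_require(out, "embeddings_train.csv", "embed")))
        test_b = embeddings_from_frame(
            pd.read_csv(_require(out, "embeddings_test.csv", "embed")))
        if config.classification.classifier == "centroid":
            cents = classifiers.fit_centroids(train_b)
            pred = classifiers.centroid_predict_batch(cents, test_b.vectors)
        else:
            knn = classifiers.fit_knn(train_b, k=config.classification.k)
            pred = classifiers.knn_predict_batch(knn, test_b.vectors)
        classifiers.predictions_to_frame(
            test_b.source_ids, test_b.labels, pred).to_csv(
            os.path.join(out, "predictions.csv"), index=False)
        return _STAGE_OUTPUTS["classify"]

    if stage == "explain":
        model = EmbeddingModel.load(_require(out, "checkpoint.npz", "train"))
        train_b = embeddings_from_frame(
            pd.read_csv(_require(out, "embeddings_train.csv", "embed")))
        cents = classifiers.fit_centroids(train_b) if model.mode == "embedding" else None
        test_ds = _load_filtered(config, "test")
        heat_dir = os.path.join(out, "heatmaps")
        os.makedirs(heat_dir, exist_ok=True)
        written = 0
        for i, im in enumerate(test_ds):
            if im.label != "sickle" or written >= config.gradcam.n_examples:
                continue
            hm = gradcam(model, im, class_index=1, centroids=cents)
            blended = overlay(im, hm, opacity=config.gradcam.opacity)
            iio.imwrite(os.path.join(heat_dir, f"heatmap_{i:04d}.png"), blended)
            written += 1
        return _STAGE_OUTPUTS["explain"]

    if stage == "report":
        pred = pd.read_csv(_require(out, "predictions.csv", "classify"))
        mset = metrics.evaluate(pred["true_label"], pred["predicted_label"])
        history = pd.read_csv(_require(out, "history.csv", "train"))
        tcfg = TrainConfig(loss=config.model.loss, epochs=config.training.epochs,
                           batch_size=config.training.batch_size,
                           lr0=config.training.lr0)
        row = {
            "network": config.model.backbone,
            "loss": config.model.loss,
            "epoch": config.training.epochs,
            "batch_size": tcfg.batch_size,
            "learn_rate": config.training.lr0,
            "val_accuracy": round(float(history["val_acc"].iloc[-1]), 3)
            if len(history) else float("nan"),
            "test_accuracy": round(mset.accuracy, 3),
            "precision": round(mset.precision, 3),
            "recall": round(mset.recall, 3),
            "f1": round(mset.f1, 3),
        }
        pd.DataFrame([row], columns=metrics.GRID_COLUMNS).to_csv(
            os.path.join(out, "results.csv"), index=False)
        return _STAGE_OUTPUTS["report"]

    raise AssertionError(stage)


def run_all(config: PipelineConfig, force: bool = False) -> List[str]:
    """Run every stage in dependency order; skip completed ones unless forced."""
    ran = []
    for stage in STAGES:
        if not force and stage_done(config, stage):
            logger.info("stage %s: skipped (outputs present)", stage)
            continue
        run_stage(stage, config)
        ran.append(stage)
    return ran
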