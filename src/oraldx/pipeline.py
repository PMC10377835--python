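"""End-to-end diagnosis pipeline and its evaluation harness.

Orchestrates the full chain on a labeled image set:

    preprocess -> segment -> extract features -> (train split only)
    select features -> tune + train SVM -> evaluate on held-out images

Every random stage draws its seed from the single master seed, so a run is
exactly reproducible; feature selection and hyperparameter tuning see only
the training rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .features import FEATURE_ORDER, extract_all
from .metrics import ConfusionCounts, MetricsReport, compute_metrics, confusion
from .optimizer import CSOConfig
from .preprocess import CLAHEConfig, preprocess_image
from .segmentation import segment_image
from .selection import LabeledFeatureTable, SelectionMask, select_features
from .svm import TuningResult, acso_tune, predict

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the end-to-end run, with one master seed."""

    median_window: int = 7
    clahe: CLAHEConfig = field(default_factory=CLAHEConfig)
    seg_k: int = 2
    seg_w_lower: float = 0.7
    seg_window: int = 4
    seg_levels: int = 8
    selection_cfg: CSOConfig = field(
        default_factory=lambda: CSOConfig(n=30, iterations=60)
    )
    selection_w1: float = 0.6
    selection_w2: float = 0.4
    tuning_cfg: CSOConfig = field(
        default_factory=lambda: CSOConfig(n=20, iterations=30)
    )
    folds: int = 5
    test_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class PipelineResult:
    metrics: MetricsReport
    counts: ConfusionCounts
    mask: SelectionMask
    tuning: TuningResult
    table: LabeledFeatureTable
    train_indices: np.ndarray
    test_indices: np.ndarray
    y_pred: np.ndarray

    def metrics_json(self) -> str:
        payload = self.metrics.as_dict()
        payload["per_class_counts"] = {
            str(k): {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
            for k, c in self.counts.per_class.items()
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def extract_feature_table(
    images,
    labels,
    cfg: PipelineConfig | None = None,
) -> tuple[LabeledFeatureTable, np.ndarray]:
    """Preprocess, segment and featurize a list of images.

    Returns the labeled feature table and the indices of the images that
    survived (per-image failures are logged and skipped).
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    seg_seeds = rng.integers(0, 2**31, size=len(images))
    rows, kept = [], []
    for i, img in enumerate(images):
        try:
            pre = preprocess_image(img, cfg.median_window, cfg.clahe)
            mask = segment_image(
                pre,
                k=cfg.seg_k,
                w_lower=cfg.seg_w_lower,
                seed=int(seg_seeds[i]),
                window=cfg.seg_window,
                levels=cfg.seg_levels,
            )
            rows.append(extract_all(pre, mask))
            kept.append(i)
        except Exception:  # noqa: BLE001 - a bad image must not kill the run
            logger.exception("skipping image %d (feature extraction failed)", i)
    if not rows:
        raise RuntimeError("no image produced a usable feature vector")
    values = np.array([[r[name] for name in FEATURE_ORDER] for r in rows])
    table = LabeledFeatureTable(
        values, np.asarray(labels)[kept], tuple(FEATURE_ORDER)
    )
    return table, np.array(kept)


def run_pipeline(
    images,
    labels,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Full train/evaluate run on a labeled image set.

    The split is stratified; selection and tuning run on training rows
    only, and the metrics are computed on the held-out images.
    """
    cfg = cfg or PipelineConfig()
    labels = np.asarray(labels)
    for cls in (-1, 1):
        if int((labels == cls).sum()) < 2:
            raise ValueError("need at least 2 images per class")

    table, kept = extract_feature_table(images, labels, cfg)
    for cls in (-1, 1):
        if int((table.labels == cls).sum()) < 2:
            raise RuntimeError("fewer than 2 usable images left in a class")

    seed_rng = np.random.default_rng(cfg.seed + 1)
    split_seed, select_seed, tune_seed = (
        int(s) for s in seed_rng.integers(0, 2**31, size=3)
    )
    idx = np.arange(len(table.labels))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=cfg.test_fraction,
        stratify=table.labels,
        random_state=split_seed % (2**32 - 1),
    )
    train = table.subset_rows(train_idx)

    mask, _cost = select_features(
        train,
        cfg=cfg.selection_cfg,
        w1=cfg.selection_w1,
        w2=cfg.selection_w2,
        folds=cfg.folds,
        seed=select_seed,
    )
    tuning = acso_tune(
        train, mask, cfg=cfg.tuning_cfg, folds=cfg.folds, seed=tune_seed
    )
    y_pred, _dec = predict(tuning.model, table.values[test_idx])
    counts = confusion(table.labels[test_idx].tolist(), y_pred.tolist(), labels=[-1, 1])
    report = compute_metrics(counts)

    result = PipelineResult(
        metrics=report,
        counts=counts,
        mask=mask,
        tuning=tuning,
        table=table,
        train_indices=train_idx,
        test_indices=test_idx,
        y_pred=y_pred,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.table.to_dataframe().to_csv(out_dir / "features.csv", index=False)
    mask_payload = {
        name: int(bit)
        for name, bit in zip(result.table.feature_names, result.mask.bits)
    }
    (out_dir / "selected_features.json").write_text(
        json.dumps(mask_payload, sort_keys=True, indent=2)
    )
    (out_dir / "metrics.json").write_text(result.metrics_json())
    model_payload = {
        "C": result.tuning.C,
        "gamma": result.tuning.gamma,
        "tuning_mse": result.tuning.mse,
        "scaler_mean": result.tuning.model.scaler_mean.tolist(),
        "scaler_scale": result.tuning.model.scaler_scale.tolist(),
        "feature_indices": result.tuning.model.feature_indices.tolist(),
    }
    (out_dir / "model.json").write_text(json.dumps(model_payload, sort_keys=True, indent=2))
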