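"""End-to-end orchestration and evaluation metrics.

Composes the stages: synthesize (or load) waveforms -> optionally pick
the VMD mode count by sample entropy -> encode to color-polyline images
over a shared background -> stratified train/test split -> train the
MobileViT-style classifier -> confusion-matrix metrics.  The slight
crack class (label 0) is the positive detection target by default.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoder import (
    MASTER_PALETTE, EncodedImage, EncoderConfig, downsample_transform,
    encode_dataset,
)
from .entropy import SampEnConfig, select_M
from .nn.train import ViTConfig, predict_labels, small_vit_config, train
from .signal_io import UltrasoundRecord, load_dataset
from .synth import EchoModelParams, generate_dataset
from .vmd import VMDConfig

__all__ = [
    "Metrics", "RunConfig", "compute_metrics", "f1_from_precision_recall",
    "split_dataset", "evaluate_predictions", "run_pipeline", "sweep_colors",
]

logger = logging.getLogger("sonocrack")


@dataclass
class Metrics:
    """Confusion counts and the derived proportions.

    A ratio with zero denominator is reported as ``None`` (with a
    warning at construction), never silently as 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    f1: float | None
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "accuracy": self.accuracy,
        }

    def format_percent(self) -> dict:
        """Table-style view: percentages to one decimal."""
        fmt = lambda v: None if v is None else f"{100 * v:.1f}%"
        return {
            "precision": fmt(self.precision), "recall": fmt(self.recall),
            "f1": fmt(self.f1), "accuracy": fmt(self.accuracy),
        }


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> Metrics:
    """Precision, recall, F1 and accuracy from confusion counts."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("confusion counts sum to zero")

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return None
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
        if precision is not None and recall is not None:
            warnings.warn("F1 undefined (precision + recall = 0)", stacklevel=2)
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(tp, fp, fn, tn, precision, recall, f1, (tp + tn) / total)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        raise ValueError("precision + recall must be positive")
    return 2 * precision * recall / (precision + recall)


def split_dataset(
    images: list[EncodedImage], ratio: float = 0.8, seed: int = 0
) -> tuple[list[EncodedImage], list[EncodedImage]]:
    """Stratified shuffle split; per-class train count = round(ratio * size).

    Rounding is to the nearest integer with ties up.  The two parts are
    disjoint and exhaustive; both classes must have >= 2 members.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    labels = sorted({img.label for img in images})
    rng = np.random.default_rng(seed)
    train_set: list[EncodedImage] = []
    test_set: list[EncodedImage] = []
    for cls in labels:
        members = [img for img in images if img.label == cls]
        if len(members) < 2:
            raise ValueError(f"class {cls} has fewer than 2 images")
        n_train = int(math.floor(ratio * len(members) + 0.5))
        n_train = min(max(n_train, 1), len(members) - 1)
        order = rng.permutation(len(members))
        train_set.extend(members[i] for i in order[:n_train])
        test_set.extend(members[i] for i in order[n_train:])
    return train_set, test_set


def evaluate_predictions(
    true_labels: np.ndarray,
    pred_labels: np.ndarray,
    positive_label: int = 0,
) -> Metrics:
    """Confusion-matrix metrics with the crack class positive by default."""
    t = np.asarray(true_labels) == positive_label
    p = np.asarray(pred_labels) == positive_label
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    return compute_metrics(tp, fp, fn, tn)


@dataclass
class RunConfig:
    """All stage configurations plus the master seed.

    ``seed`` derives every stage seed (data generation, background
    selection, split shuffle, training) so one integer reproduces the
    whole run.  The default classifier configuration is the reduced
    64 x 64 plan; pass a full-scale :class:`ViTConfig` to override.
    """

    echo_params: EchoModelParams = field(default_factory=EchoModelParams)
    vmd_config: VMDConfig = field(default_factory=VMDConfig)
    sampen_config: SampEnConfig = field(default_factory=SampEnConfig)
    encoder_config: EncoderConfig = field(default_factory=EncoderConfig)
    vit_config: ViTConfig = field(default_factory=small_vit_config)
    n_intact: int = 296
    n_crack: int = 304
    n_background_per_class: int = 30
    split_ratio: float = 0.8
    select_mode_count: bool = False
    positive_label: int = 0
    seed: int = 0
    dataset_dir: str | None = None      # load waveforms instead of synthesizing
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie strictly between 0 and 1")


def _stage_seeds(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    return {name: int(rng.integers(0, 2**31 - 1))
            for name in ("data", "background", "split", "train")}


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute the full chain and return a report dictionary.

    The report carries the resolved seeds, the selected or configured
    mode count, per-epoch training history, and held-out metrics.  With
    ``output_dir`` set, the metrics JSON, the background and every
    encoded image are also written to disk.
    """
    config = config or RunConfig()
    seeds = _stage_seeds(config.seed)
    stage = "synthesize"
    try:
        if config.dataset_dir is not None:
            records = load_dataset(config.dataset_dir)
        else:
            records = generate_dataset(
                config.n_intact, config.n_crack, config.echo_params,
                seed=seeds["data"],
            )
        logger.info("stage %s: %d records", stage, len(records))

        vmd_config = config.vmd_config
        selected_m = vmd_config.n_modes
        if config.select_mode_count:
            stage = "select_M"
            selected_m = select_M(
                records[0].amplitudes, vmd_config, config.sampen_config
            )
            vmd_config = VMDConfig(
                n_modes=selected_m, alpha=vmd_config.alpha, tau=vmd_config.tau,
                eps=vmd_config.eps, max_iter=vmd_config.max_iter,
                init_omega=vmd_config.init_omega,
            )
            logger.info("stage %s: M = %d", stage, selected_m)

        stage = "encode"
        # downsample each raster to the classifier input size as soon as it
        # is drawn, so the run never holds hundreds of full canvases; when
        # an output directory is requested the full raster is written to
        # disk first
        small = downsample_transform(
            config.vit_config.input_size, config.vit_config.crop_box
        )
        if config.output_dir is None:
            transform = small
        else:
            out = Path(config.output_dir)
            for sub in ("intact", "crack"):
                (out / sub).mkdir(parents=True, exist_ok=True)

            def transform(image):
                sub = "intact" if image.label == 1 else "crack"
                image.save(out / sub / f"{image.sample_id}.png")
                return small(image)
        background, images = encode_dataset(
            records, vmd_config, config.encoder_config,
            n_background_per_class=config.n_background_per_class,
            seed=seeds["background"],
            transform=transform,
        )
        logger.info("stage %s: %d images", stage, len(images))

        stage = "split"
        train_images, test_images = split_dataset(
            images, config.split_ratio, seed=seeds["split"]
        )

        stage = "train"
        vit_config = ViTConfig(**{**vars(config.vit_config), "seed": seeds["train"]})
        model, history = train(train_images, vit_config)

        stage = "evaluate"
        true_labels = np.array([img.label for img in test_images])
        pred = predict_labels(model, test_images, vit_config)
        metrics = evaluate_predictions(true_labels, pred, config.positive_label)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    report = {
        "seeds": {"master": config.seed, **seeds},
        "n_records": len(records),
        "n_modes": selected_m,
        "n_train": len(train_images),
        "n_test": len(test_images),
        "history": history,
        "metrics": metrics.to_dict(),
        "metrics_percent": metrics.format_percent(),
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(json.dumps(report, indent=2))
        if background is not None:
            background.save(out / "background.png")
    return report


def sweep_colors(b_values: list[int], config: RunConfig | None = None) -> list[dict]:
    """Re-encode and retrain per color count B; returns one row per B.

    All rows reuse the same underlying signals, background selection,
    split shuffle and training seed, so rows differ only through the
    palette size (polyline geometry is identical across B).
    """
    config = config or RunConfig()
    if max(b_values) > len(MASTER_PALETTE):
        raise ValueError(
            f"B up to {len(MASTER_PALETTE)} supported by the master palette"
        )
    rows = []
    for b in b_values:
        enc = EncoderConfig(
            n_colors=b,
            palette=list(MASTER_PALETTE),
            image_width=config.encoder_config.image_width,
            image_height=config.encoder_config.image_height,
            origin_x=config.encoder_config.origin_x,
            origin_y=config.encoder_config.origin_y,
            draw_width=config.encoder_config.draw_width,
            draw_top=config.encoder_config.draw_top,
            line_width=config.encoder_config.line_width,
        )
        sub = RunConfig(**{**vars(config), "encoder_config": enc,
                           "output_dir": None})
        report = run_pipeline(sub)
        rows.append({"B": b, "accuracy": report["metrics"]["accuracy"],
                     "metrics": report["metrics"]})
    return rows
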