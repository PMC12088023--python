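"""Ablation harness: run the pipeline over strategy × magnification cells.

Each strategy names a whole training-and-inference setting:

========== ============================ ==============================
strategy   training data                inference
========== ============================ ==============================
none       original images              single-image (K = 1)
routine    photometric augmentation     single-image (K = 1)
quarter    2×2 grid division (×4)       2×2 tiling + average fusion
sixteenth  4×4 grid division (×16)      4×4 tiling + average fusion
========== ============================ ==============================

Test images are never photometrically augmented in any strategy. Every run
directory is self-describing: config snapshot, seed registry, per-cell
predictions, confusion counts and the metrics grid are all written under
``output_dir`` so a run can be replayed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .augmentation import AugmentConfig, augment_training_set, expand_training_set
from .backbone import extract_features, make_backbone
from .dataset_io import scan_dataset, split_dataset, write_manifest
from .fusion import predict_batch
from .head import TrainConfig, train_head
from .metrics import (
    ConfusionMatrix,
    MetricsReport,
    confusion,
    render_report,
    report_from_confusion,
)
from .synthetic import SyntheticSpec, generate_dataset
from .types import Magnification, SplitSpec

logger = logging.getLogger(__name__)

STRATEGIES: Dict[str, Tuple[bool, int]] = {
    # strategy -> (routine augmentation?, grid n)
    "none": (False, 1),
    "routine": (True, 1),
    "quarter": (False, 2),
    "sixteenth": (False, 4),
}


@dataclass
class ExperimentConfig:
    """Full specification of an ablation run."""

    dataset: Union[str, SyntheticSpec]
    layout: str = "two_class_folders"
    magnifications: Sequence[str] = ()
    strategies: Sequence[str] = ("none", "routine", "quarter", "sixteenth")
    backbone: str = "fixture"
    backbone_seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    output_dir: str = "runs/experiment"


def validate_config(config: ExperimentConfig) -> List[str]:
    """Return a list of validation errors (empty when the config is ok)."""
    errors = []
    for s in config.strategies:
        if s not in STRATEGIES:
            errors.append(
                f"undefined strategy {s!r}; valid: {sorted(STRATEGIES)}"
            )
    if not config.strategies:
        errors.append("no strategies requested")
    if config.layout not in ("breakhis", "two_class_folders"):
        errors.append(f"unknown layout {config.layout!r}")
    for m in config.magnifications:
        if Magnification.from_string(m) is Magnification.UNKNOWN:
            errors.append(f"unknown magnification {m!r}")
    if isinstance(config.dataset, str) and not Path(config.dataset).exists():
        errors.append(f"dataset path does not exist: {config.dataset}")
    if config.backbone not in ("fixture", "inception_resnet_v2"):
        errors.append(f"unknown backbone {config.backbone!r}")
    return errors


def _resolve_records(config: ExperimentConfig):
    if isinstance(config.dataset, SyntheticSpec):
        return generate_dataset(config.dataset)
    return scan_dataset(config.dataset, layout=config.layout)


def run_cell(
    records,
    strategy: str,
    config: ExperimentConfig,
    magnification: Optional[str],
    out_dir: Path,
) -> MetricsReport:
    """Run one (magnification, strategy) cell end to end."""
    use_routine, n = STRATEGIES[strategy]
    split = split_dataset(records, config.split)
    backbone = make_backbone(config.backbone, seed=config.backbone_seed)

    train_images = split.train
    if use_routine:
        train_images = augment_training_set(
            train_images, config.augment, seed=config.train.seed
        )
    train_tiles = expand_training_set(train_images, n)
    feats = extract_features(backbone, train_tiles)
    head, loss_history = train_head(feats, config.train)

    preds = predict_batch(head, backbone, split.test, n)
    cm = confusion(
        [p.true_label for p in preds], [p.predicted_label for p in preds]
    )
    report = report_from_confusion(
        cm, magnification=magnification, strategy=strategy
    )

    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "parent_id": [p.parent_id for p in preds],
            "p_benign": [p.fused.p_benign for p in preds],
            "p_malignant": [p.fused.p_malignant for p in preds],
            "predicted_label": [p.predicted_label.value for p in preds],
            "true_label": [p.true_label.value for p in preds],
            "K": [p.K for p in preds],
        }
    ).to_csv(out_dir / "predictions.csv", index=False)
    pd.DataFrame([dataclasses.asdict(cm)]).to_csv(
        out_dir / "confusion.csv", index=False
    )
    (out_dir / "loss_history.json").write_text(json.dumps(loss_history))
    write_manifest(split.train + split.test, out_dir / "split_manifest.csv",
                   split=split)
    return report


def run_experiment(config: ExperimentConfig) -> List[MetricsReport]:
    """Run every (magnification, strategy) cell and emit the metrics grid.

    A failing cell is logged and skipped; the remaining cells proceed.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid experiment config: " + "; ".join(errors))
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    _write_config_snapshot(config, out_root / "config.json")

    all_records = _resolve_records(config)
    mags = list(config.magnifications) or [None]
    reports: List[MetricsReport] = []
    for mag in mags:
        if mag is None:
            records = all_records
        else:
            target = Magnification.from_string(mag)
            records = [r for r in all_records if r.magnification is target]
        for strategy in config.strategies:
            cell = out_root / f"{mag or 'all'}_{strategy}"
            try:
                reports.append(
                    run_cell(records, strategy, config, mag, cell)
                )
            except Exception:
                logger.exception(
                    "cell (%s, %s) failed; continuing", mag, strategy
                )
    if reports:
        render_report(reports, out_root / "metrics.csv", fmt="csv")
        render_report(reports, out_root / "metrics.md", fmt="markdown")
    return reports


def _write_config_snapshot(config: ExperimentConfig, path: Path) -> None:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, tuple):
            return list(obj)
        return str(obj)

    path.write_text(json.dumps(dataclasses.asdict(config), default=enc, indent=2))


def config_from_dict(raw: dict) -> ExperimentConfig:
    """Build an ExperimentConfig from a plain (YAML-loaded) mapping."""
    raw = dict(raw)
    dataset = raw.pop("dataset")
    if isinstance(dataset, dict):
        dataset = SyntheticSpec(**dataset)
    train_raw = raw.pop("train", {})
    if "hidden_sizes" in train_raw:
        train_raw["hidden_sizes"] = tuple(train_raw["hidden_sizes"])
    train = TrainConfig(**train_raw)
    split = SplitSpec(**raw.pop("split", {}))
    aug_raw = raw.pop("augment", {})
    if "ops" in aug_raw:
        aug_raw["ops"] = tuple(aug_raw["ops"])
    augment = AugmentConfig(**aug_raw)
    return ExperimentConfig(
        dataset=dataset, train=train, split=split, augment=augment, **raw
    )
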