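"""Desk-scale ablation harness: effect of cohort size and of rotational
minority-class augmentation.

Each cell of a report is a fully seeded run of the whole pipeline —
simulate a labeled cohort, encode trips to binary grids, stratified
split, optional minority augmentation of the *training split only*,
train, evaluate — so every number is traceable to its seeds.  Paired
conditions (with / without augmentation) share cohorts, splits and model
initialization exactly; the test split is bit-identical across the pair,
so any metric difference is attributable to the training data alone.

More data reliably helps.  The augmentation effect is architecture- and
data-dependent: on cohorts whose trip orientations are uniformly random
(so rotations add no orientation information), minority rotation acts
as correlated oversampling — it consistently benefits the CNN but can
hurt the ViT and ResNet.  See docs/methods.md for the analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dataset_builder import GridDataset, augment_minority, split_dataset, stack_dataset
from .grid_encoding import GridSpec, encode_trips
from .models import build_model
from .synthetic_trips import DEFAULT_MIX, SimConfig, generate_cohort, hardened_config
from .training_eval import Metrics, TrainConfig, evaluate, train

__all__ = [
    "PipelineConfig",
    "RunResult",
    "ExperimentReport",
    "run_pipeline",
    "run_data_size_ablation",
    "run_augmentation_ablation",
    "plot_report",
]

#: Reduced ViT depth used at desk scale; full depth stays available via
#: model_overrides={"n_encoder_layers": 6}.
SMALL_VIT_LAYERS = 2


@dataclass(frozen=True)
class PipelineConfig:
    """One end-to-end run: cohort -> grids -> split -> (augment) -> train -> eval."""

    n_normal: int = 160
    n_abnormal: int = 80
    grid_hw: tuple[int, int] = (64, 64)
    test_fraction: float = 0.2
    augment: bool = False
    augment_angles: tuple[int, ...] = (90, 180, 270)
    hardened: bool = False
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    mix: Optional[dict] = None


@dataclass
class RunResult:
    model: str
    seed: int
    config: PipelineConfig
    metrics: Metrics
    loss_history: list[float]
    train_size: int
    test_size: int
    test_fingerprint: str


@dataclass
class ExperimentReport:
    """Per (model x condition) cell: mean macro / weighted F1 with the
    seeds and cohort sizes that produced them."""

    kind: str
    cells: dict[str, dict]

    def to_json(self, path: str | Path) -> None:
        with open(Path(path), "w", encoding="utf-8") as fh:
            json.dump({"kind": self.kind, "cells": self.cells}, fh, indent=2)


def _fingerprint(dataset: GridDataset) -> str:
    h = hashlib.sha256()
    h.update(dataset.grids.tobytes())
    h.update(dataset.labels.tobytes())
    return h.hexdigest()[:16]


def _model_overrides(model_name: str, overrides: Optional[dict]) -> dict:
    out = dict(overrides or {})
    if model_name == "vit":
        out.setdefault("n_encoder_layers", SMALL_VIT_LAYERS)
    return out


def build_split(
    config: PipelineConfig, seed: int
) -> tuple[GridDataset, GridDataset]:
    """Simulate, encode and split a cohort (augmentation not yet applied)."""
    base = hardened_config() if config.hardened else SimConfig()
    trips = generate_cohort(
        config.n_normal,
        config.n_abnormal,
        mix=config.mix or DEFAULT_MIX,
        seed=seed,
        base_config=base,
    )
    grids = encode_trips(trips, GridSpec(*config.grid_hw))
    dataset = stack_dataset(grids)
    return split_dataset(dataset, config.test_fraction, seed=seed)


def run_pipeline(
    model_name: str,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    model_overrides: Optional[dict] = None,
    split: Optional[tuple[GridDataset, GridDataset]] = None,
) -> RunResult:
    """Run the full pipeline once and evaluate on the held-out split.

    ``split`` lets paired conditions reuse the same cohort/split.
    """
    train_set, test_set = split if split is not None else build_split(config, seed)
    if config.augment:
        train_set = augment_minority(train_set, config.augment_angles)
    model = build_model(
        model_name,
        input_hw=config.grid_hw,
        seed=seed,
        **_model_overrides(model_name, model_overrides),
    )
    tc = TrainConfig(
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        seed=seed,
    )
    model, history = train(model, train_set, tc)
    metrics = evaluate(model, test_set)
    return RunResult(
        model=model_name,
        seed=seed,
        config=config,
        metrics=metrics,
        loss_history=history,
        train_size=len(train_set),
        test_size=len(test_set),
        test_fingerprint=_fingerprint(test_set),
    )


def run_data_size_ablation(
    sizes: Sequence[int],
    models: Sequence[str] = ("cnn", "vit"),
    seeds: Sequence[int] = (0, 1, 2),
    base_config: PipelineConfig = PipelineConfig(),
    model_overrides: Optional[dict] = None,
) -> ExperimentReport:
    """Mean macro/weighted F1 per (model, cohort size) cell.

    ``sizes`` are total cohort sizes; the normal:abnormal ratio of
    ``base_config`` is preserved.
    """
    if len(sizes) < 2:
        raise ValueError("need at least 2 cohort sizes")
    ratio = base_config.n_abnormal / (base_config.n_normal + base_config.n_abnormal)
    cells: dict[str, dict] = {}
    for size in sizes:
        n_abn = max(2, int(round(ratio * size)))
        cfg = PipelineConfig(
            **{
                **asdict(base_config),
                "n_normal": size - n_abn,
                "n_abnormal": n_abn,
            }
        )
        for model_name in models:
            results = [
                run_pipeline(model_name, cfg, seed=s, model_overrides=model_overrides)
                for s in seeds
            ]
            cells[f"{model_name}/n={size}"] = {
                "model": model_name,
                "cohort_size": size,
                "macro_f1": float(np.mean([r.metrics.macro_f1 for r in results])),
                "weighted_f1": float(np.mean([r.metrics.weighted_f1 for r in results])),
                "seeds": list(seeds),
            }
    return ExperimentReport("data_size", cells)


def run_augmentation_ablation(
    models: Sequence[str] = ("cnn", "vit", "resnet"),
    imbalance_ratio: float = 0.10,
    seeds: Sequence[int] = (0, 1, 2),
    base_config: PipelineConfig = PipelineConfig(hardened=True),
    model_overrides: Optional[dict] = None,
) -> ExperimentReport:
    """Paired with/without-augmentation runs on identical cohorts.

    ``imbalance_ratio`` is the abnormal (minority) fraction of the
    cohort and must denote a true minority (< 0.5).  Reports per-model
    mean macro/weighted F1 under both conditions and the paired deltas.
    """
    if not (0.0 < imbalance_ratio < 0.5):
        raise ValueError(f"imbalance_ratio must be in (0, 0.5), got {imbalance_ratio}")
    total = base_config.n_normal + base_config.n_abnormal
    n_abn = max(2, int(round(imbalance_ratio * total)))
    cfg_plain = PipelineConfig(
        **{
            **asdict(base_config),
            "n_normal": total - n_abn,
            "n_abnormal": n_abn,
            "augment": False,
        }
    )
    cfg_aug = PipelineConfig(**{**asdict(cfg_plain), "augment": True})

    cells: dict[str, dict] = {}
    for model_name in models:
        deltas_macro, deltas_weighted = [], []
        macro = {"augmented": [], "plain": []}
        weighted = {"augmented": [], "plain": []}
        for s in seeds:
            split = build_split(cfg_plain, seed=s)
            r_plain = run_pipeline(
                model_name, cfg_plain, seed=s, model_overrides=model_overrides, split=split
            )
            r_aug = run_pipeline(
                model_name, cfg_aug, seed=s, model_overrides=model_overrides, split=split
            )
            if r_plain.test_fingerprint != r_aug.test_fingerprint:
                raise AssertionError("paired conditions diverged on the test split")
            macro["plain"].append(r_plain.metrics.macro_f1)
            macro["augmented"].append(r_aug.metrics.macro_f1)
            weighted["plain"].append(r_plain.metrics.weighted_f1)
            weighted["augmented"].append(r_aug.metrics.weighted_f1)
            deltas_macro.append(r_aug.metrics.macro_f1 - r_plain.metrics.macro_f1)
            deltas_weighted.append(
                r_aug.metrics.weighted_f1 - r_plain.metrics.weighted_f1
            )
        cells[model_name] = {
            "model": model_name,
            "cohort_size": total,
            "minority_fraction": n_abn / total,
            "macro_f1": {k: float(np.mean(v)) for k, v in macro.items()},
            "weighted_f1": {k: float(np.mean(v)) for k, v in weighted.items()},
            "mean_macro_f1_delta": float(np.mean(deltas_macro)),
            "mean_weighted_f1_delta": float(np.mean(deltas_weighted)),
            "paired_macro_deltas": [float(d) for d in deltas_macro],
            "seeds": list(seeds),
        }
    return ExperimentReport("augmentation", cells)


def plot_report(report: ExperimentReport, path: str | Path) -> None:
    """Grouped bar chart of macro/weighted F1 per cell (SVG or PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(report.cells)
    if report.kind == "augmentation":
        macro = [report.cells[n]["macro_f1"]["augmented"] for n in names]
        macro_plain = [report.cells[n]["macro_f1"]["plain"] for n in names]
        x = np.arange(len(names))
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(x - 0.2, macro_plain, 0.4, label="macro F1, no augmentation")
        ax.bar(x + 0.2, macro, 0.4, label="macro F1, augmented")
    else:
        macro = [report.cells[n]["macro_f1"] for n in names]
        weighted = [report.cells[n]["weighted_f1"] for n in names]
        x = np.arange(len(names))
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(x - 0.2, macro, 0.4, label="macro F1")
        ax.bar(x + 0.2, weighted, 0.4, label="weighted F1")
    ax.set_xticks(x)
    ax.set_xticklabels(names, rotation=30, ha="right")
    ax.set_ylim(0, 1.05)
    ax.set_ylabel("F1 score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(Path(path))
    plt.close(fig)
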