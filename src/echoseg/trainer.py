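"""Training and evaluation loops.

The default recipe follows the published protocol: Adam (momentum 0.9),
learning rate 1e-4 decayed to 0.9× at epochs 100 and 150, batch size 16,
300 epochs, 256×256 inputs, Lovász-Softmax loss (deep supervision sums the
loss over all four heads).  Small smoke configurations override the sizes,
step counts and learning rate; the recipe constants stay the defaults.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import metrics as M
from .network import (
    ModelConfig,
    SegmentationModel,
    build_model,
    forward_predict,
    load_checkpoint,
    save_checkpoint,
)
from .nn import Adam, Tensor, add_n
from .nn.losses import cross_entropy_op, lovasz_softmax_op
from .phantom import CLASS_NAMES

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "train", "evaluate", "run_ablation", "foreground_dice"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    lr_decay_factor: float = 0.9
    decay_epochs: tuple = (100, 150)
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 16
    epochs: int = 300
    image_size: int = 256
    loss: str = "lovasz"  # "lovasz" | "lovasz+ce"
    ce_weight: float = 0.0
    loss_classes: str = "all"  # average over all classes (the definition) or "present"
    seed: int = 0
    val_fraction: float = 0.1
    eval_every_steps: int | None = None  # default: once per epoch
    max_steps: int | None = None
    early_stop_fg_dice: float | None = None  # stop once train-set fg Dice reaches this

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("lr, batch_size and epochs must be positive")
        if list(self.decay_epochs) != sorted(self.decay_epochs):
            raise ValueError("decay_epochs must be sorted")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")


def _lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    passed = sum(1 for e in cfg.decay_epochs if epoch >= e)
    return cfg.lr * cfg.lr_decay_factor**passed


def foreground_dice(cm: M.ConfusionMatrix) -> float:
    """Mean Dice over the five non-background classes."""
    return float(np.mean([M.dice(cm, c) for c in range(1, cm.num_classes)]))


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    images, labels = dataset
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    if len(images) == 0:
        raise ValueError("empty dataset")
    if images.shape[:3] != labels.shape[:3]:
        raise ValueError("images/labels shape mismatch")
    return images, labels


def _loss_of(model, xb: Tensor, yb: np.ndarray, cfg: TrainConfig):
    heads = model(xb)
    terms = [lovasz_softmax_op(h, yb, classes=cfg.loss_classes) for h in heads]
    loss = add_n(terms)
    if cfg.loss == "lovasz+ce" and cfg.ce_weight > 0:
        loss = add_n([loss] + [cross_entropy_op(h, yb) * cfg.ce_weight for h in heads])
    return loss


def train(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    dataset,
    out_dir: str | Path | None = None,
    val_dataset=None,
) -> tuple[SegmentationModel, list[dict]]:
    """Train a model; returns (model restored to its best validation state,
    history).

    ``dataset`` is an (images, labels) pair of stacked arrays.  When no
    explicit validation set is given, the trailing ``val_fraction`` of the
    samples is held out (the caller is responsible for any sweep-level
    grouping).  History rows carry epoch, step, lr, loss and validation
    scores; they are written as JSON-lines when ``out_dir`` is given.
    """
    images, labels = _as_arrays(dataset)
    n = len(images)
    if val_dataset is not None:
        val_images, val_labels = _as_arrays(val_dataset)
    else:
        n_val = int(round(train_cfg.val_fraction * n))
        if n_val > 0:
            val_images, val_labels = images[n - n_val :], labels[n - n_val :]
            images, labels = images[: n - n_val], labels[: n - n_val]
            n = len(images)
        else:  # tiny smoke runs validate on the training images
            val_images, val_labels = images, labels

    model = build_model(model_cfg, seed=train_cfg.seed)
    opt = Adam(model.parameters(), lr=train_cfg.lr, beta1=train_cfg.beta1, beta2=train_cfg.beta2)
    rng = np.random.default_rng(train_cfg.seed + 1)

    history: list[dict] = []
    best = {"val_miou": -1.0, "state": model.state_dict()}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "train_config.json").write_text(
            json.dumps({"model": asdict(model_cfg), "train": asdict(train_cfg)},
                       indent=2, sort_keys=True, default=list)
        )

    step = 0
    eval_every = train_cfg.eval_every_steps
    stop = False
    for epoch in range(train_cfg.epochs):
        if stop:
            break
        opt.lr = _lr_at_epoch(train_cfg, epoch)
        order = rng.permutation(n)
        for lo in range(0, n, train_cfg.batch_size):
            idx = order[lo : lo + train_cfg.batch_size]
            xb = Tensor(images[idx][..., None])
            model.train()
            loss = _loss_of(model, xb, labels[idx], train_cfg)
            loss_val = float(np.asarray(loss.data).item())
            if not np.isfinite(loss_val):
                raise RuntimeError(f"non-finite loss at step {step}: {loss_val}")
            loss.backward()
            opt.step()
            opt.zero_grad()
            step += 1
            end_of_epoch = lo + train_cfg.batch_size >= n
            if (eval_every and step % eval_every == 0) or (not eval_every and end_of_epoch):
                names = (
                    CLASS_NAMES
                    if model_cfg.num_classes == len(CLASS_NAMES)
                    else tuple(f"class{c}" for c in range(model_cfg.num_classes))
                )
                rep = evaluate(model, (val_images, val_labels), class_names=names)
                row = {
                    "epoch": epoch,
                    "step": step,
                    "lr": opt.lr,
                    "loss": loss_val,
                    "val_miou": rep.aggregates["miou"],
                    "val_fg_dice": rep.aggregates["mean_dice_foreground"],
                }
                history.append(row)
                if out_dir is not None:
                    with open(out_dir / "history.jsonl", "a") as fh:
                        fh.write(json.dumps(row, sort_keys=True) + "\n")
                if rep.aggregates["miou"] > best["val_miou"]:
                    best = {"val_miou": rep.aggregates["miou"], "state": model.state_dict()}
                if (
                    train_cfg.early_stop_fg_dice is not None
                    and row["val_fg_dice"] >= train_cfg.early_stop_fg_dice
                ):
                    stop = True
                    break
            if train_cfg.max_steps is not None and step >= train_cfg.max_steps:
                stop = True
                break

    model.load_state_dict(best["state"])
    if out_dir is not None:
        save_checkpoint(model, out_dir / "best.npz")
    return model, history


PredictFn = Callable[[np.ndarray], np.ndarray]


def evaluate(
    model: SegmentationModel | str | Path | PredictFn,
    dataset,
    class_names: Sequence[str] = CLASS_NAMES,
    chunk: int = 8,
) -> M.MetricsReport:
    """Aggregate Dice/mIOU/PA and the per-class CPA table over a dataset.

    ``model`` may be a trained model, a checkpoint path, or any callable
    mapping an image batch to predicted label maps (e.g. an identity oracle
    in tests).  The confusion matrix is accumulated over all pixels and kept
    on the report for persistence.
    """
    images, labels = _as_arrays(dataset)
    if isinstance(model, (str, Path)):
        model = load_checkpoint(model)
    C = len(class_names)
    cm = M.ConfusionMatrix(np.zeros((C, C), dtype=np.int64), C)
    for lo in range(0, len(images), chunk):
        batch = images[lo : lo + chunk]
        if isinstance(model, SegmentationModel):
            if model.cfg.num_classes != C:
                raise ValueError(
                    f"model predicts {model.cfg.num_classes} classes, report expects {C}"
                )
            _, pred = forward_predict(model, batch)
        else:
            pred = np.asarray(model(batch))
        cm = cm + M.confusion_matrix(pred, labels[lo : lo + chunk], C)
    report = M.compute_report(cm, list(class_names))
    report.aggregates["mean_dice_foreground"] = float(
        np.mean([M.dice(cm, c) for c in range(1, C)])
    )
    return report


# ---------------------------------------------------------------------------
# ablation grids (decode modes / PPM bins / module on-off)


def decode_mode_grid(base: ModelConfig) -> list[tuple[str, ModelConfig]]:
    return [(mode, replace(base, decode_mode=mode)) for mode in ("L2", "L3", "L4", "DS")]


def ppm_bins_grid(base: ModelConfig) -> list[tuple[str, ModelConfig]]:
    return [
        (str(bins), replace(base, ppm_bins=bins, ppm_enabled=True))
        for bins in ((1, 2, 3, 4), (1, 2, 3, 6), (1, 2, 4, 8))
    ]


def modules_grid(base: ModelConfig) -> list[tuple[str, ModelConfig]]:
    return [
        ("baseline", replace(base, ppm_enabled=False, ag_enabled=False)),
        ("+PPM", replace(base, ppm_enabled=True, ag_enabled=False)),
        ("+AG", replace(base, ppm_enabled=False, ag_enabled=True)),
        ("+PPM+AG", replace(base, ppm_enabled=True, ag_enabled=True)),
    ]


def run_ablation(
    grid: list[tuple[str, ModelConfig]],
    train_cfg: TrainConfig,
    train_dataset,
    test_dataset,
    out_dir: str | Path | None = None,
) -> list[dict]:
    """Train/evaluate one row per configuration; returns the result table."""
    rows = []
    for name, mcfg in grid:
        model, _ = train(mcfg, train_cfg, train_dataset)
        rep = evaluate(model, test_dataset)
        row = {
            "name": name,
            "decode_mode": mcfg.decode_mode,
            "ppm": mcfg.ppm_enabled,
            "ag": mcfg.ag_enabled,
            "ppm_bins": list(mcfg.ppm_bins),
            "dice": rep.aggregates["mean_dice"],
            "fg_dice": rep.aggregates["mean_dice_foreground"],
            "miou": rep.aggregates["miou"],
            "pa": rep.aggregates["pixel_accuracy"],
        }
        logger.info("ablation %s: %s", name, row)
        rows.append(row)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "ablation.json").write_text(json.dumps(rows, indent=2, sort_keys=True))
        import csv

        with open(out_dir / "ablation.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            w.writeheader()
            w.writerows(rows)
    return rows
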