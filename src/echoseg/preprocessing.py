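"""Frame preparation and training-time augmentation.

Pipeline for real or synthetic frames: optional ROI crop (a configured
rectangle — interface markers on clinical frames are excluded by cropping),
resize to the network input size, rescale to [0, 1], and optional non-local
means (NLM) despeckling.  Augmentation applies one geometric transform to
the image (bilinear) and its label map (nearest-neighbour, so class indices
are never interpolated).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import transform as sktf
from skimage.restoration import denoise_nl_means

__all__ = [
    "AugmentConfig",
    "nlm_denoise",
    "augment",
    "prepare_frame",
    "write_manifest",
    "read_manifest",
    "split_manifest",
]


@dataclass(frozen=True)
class AugmentConfig:
    """Random flip / rotation / crop-scale / zoom parameters.

    Defaults: horizontal flip with probability 0.5, rotation within ±15°,
    crop-scale and zoom within 0.9–1.1 — the transform kinds follow the
    training protocol, the magnitudes are package defaults.
    """

    flip_prob: float = 0.5
    rotate_range: float = 15.0  # degrees, symmetric
    crop_scale_range: tuple = (0.9, 1.1)
    zoom_range: tuple = (0.9, 1.1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        for lo, hi in (self.crop_scale_range, self.zoom_range):
            if not 0 < lo <= hi:
                raise ValueError("ranges must be positive and ordered")
        if self.rotate_range < 0:
            raise ValueError("rotate_range must be nonnegative")


def nlm_denoise(
    image: np.ndarray, patch_size: int = 5, search_window: int = 13, h: float = 0.08
) -> np.ndarray:
    """Non-local means despeckling of a [0, 1] grayscale frame.

    ``search_window`` is the full width of the search neighbourhood and must
    be at least the patch size; ``h`` controls the weighting bandwidth
    (``h → 0`` approaches the identity).
    """
    image = np.asarray(image, dtype=np.float64)
    if search_window < patch_size:
        raise ValueError("search window smaller than patch size")
    if h <= 0:
        return image.copy()
    patch_distance = max(1, (search_window - patch_size) // 2)
    out = denoise_nl_means(
        image, patch_size=patch_size, patch_distance=patch_distance, h=h, fast_mode=True
    )
    return np.clip(out, 0.0, 1.0)


def augment(
    image: np.ndarray,
    labels: np.ndarray,
    cfg: AugmentConfig,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One random flip/rotate/zoom applied identically to image and labels.

    Deterministic for fixed (cfg, seed).  Labels are warped with
    nearest-neighbour interpolation, so the output contains no class
    indices that were absent from the input (classes may drop out when
    zoomed past the border).
    """
    image = np.asarray(image, dtype=np.float64)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError("image and labels must share a shape")
    rng = np.random.default_rng(seed)
    flip = rng.uniform() < cfg.flip_prob
    angle = rng.uniform(-cfg.rotate_range, cfg.rotate_range)
    zoom = rng.uniform(*cfg.zoom_range) * rng.uniform(*cfg.crop_scale_range)

    if flip:
        image = image[:, ::-1]
        labels = labels[:, ::-1]
    h, w = image.shape
    center = np.array([w, h]) / 2.0 - 0.5
    tf = (
        sktf.AffineTransform(translation=-center)
        + sktf.AffineTransform(rotation=np.deg2rad(angle), scale=(1.0 / zoom, 1.0 / zoom))
        + sktf.AffineTransform(translation=center)
    )
    img_out = sktf.warp(image, tf.inverse, order=1, mode="constant", cval=0.0,
                        preserve_range=True)
    lab_out = sktf.warp(labels.astype(np.float64), tf.inverse, order=0, mode="constant",
                        cval=0.0, preserve_range=True)
    return np.clip(img_out, 0.0, 1.0), lab_out.astype(labels.dtype)


def prepare_frame(
    image: np.ndarray,
    target_size: int = 256,
    roi: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Crop to the ROI rectangle ``(top, left, height, width)``, resize to
    ``target_size`` square and rescale to [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale frame")
    if roi is not None:
        top, left, height, width = roi
        if top < 0 or left < 0 or top + height > image.shape[0] or left + width > image.shape[1]:
            raise ValueError(f"ROI {roi} outside image bounds {image.shape}")
        image = image[top : top + height, left : left + width]
    if image.max() > 1.0:
        image = image / 255.0
    if image.shape != (target_size, target_size):
        image = sktf.resize(image, (target_size, target_size), order=1, mode="reflect",
                            anti_aliasing=True, preserve_range=True)
    return np.clip(image, 0.0, 1.0)


# ---------------------------------------------------------------------------
# dataset manifests: CSV of (image path, label path, sweep id, split)


def write_manifest(rows: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["image", "label", "sweep", "split"])
        w.writeheader()
        w.writerows(rows)


def read_manifest(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def split_manifest(
    entries: list[dict], train_fraction: float = 0.9, level: str = "sweep", seed: int = 0
) -> list[dict]:
    """Assign train/test splits at 9:1 by default.

    ``level="sweep"`` splits whole sweeps (prevents adjacent-frame leakage
    between splits); ``level="frame"`` splits individual frames.
    """
    rng = np.random.default_rng(seed)
    entries = [dict(e) for e in entries]
    if level == "sweep":
        sweeps = sorted({e["sweep"] for e in entries})
        order = rng.permutation(len(sweeps))
        n_train = int(round(train_fraction * len(sweeps)))
        train_ids = {sweeps[i] for i in order[:n_train]}
        for e in entries:
            e["split"] = "train" if e["sweep"] in train_ids else "test"
    elif level == "frame":
        order = rng.permutation(len(entries))
        n_train = int(round(train_fraction * len(entries)))
        train_idx = set(order[:n_train].tolist())
        for i, e in enumerate(entries):
            e["split"] = "train" if i in train_idx else "test"
    else:
        raise ValueError("level must be 'sweep' or 'frame'")
    return entries
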