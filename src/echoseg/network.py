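"""Nested U-Net with pyramid pooling and attention gates.

The backbone is a U-Net++ grid of nodes ``X[i][j]`` (depth ``i``, column
``j``): column 0 is the encoder; every decoder node receives the upsampled
deeper node ``X[i+1][j-1]`` concatenated with all same-depth predecessors
``X[i][0..j-1]`` (dense skips).  Two additions:

* **PPM** — the deepest encoder feature is average-pooled onto several grid
  sizes (default 1, 2, 3, 6), each branch channel-reduced to ``1/N`` of the
  input by a 1×1 conv, bilinearly upsampled back and concatenated with the
  input (output channels = 2× input), then fused back to the encoder width
  by a 3×3 conv.
* **AG** — at each outermost decoder column the bundle of same-depth skip
  features is multiplicatively gated by a coefficient map
  ``Q = σ(ψ(ReLU(W_x·x + W_g·g)))`` computed from the bundle and the deeper
  decoder feature (1×1 convs + BN on each path), the gating signal being
  bilinearly resampled to the bundle's size.

Prediction heads (1×1 conv to ``num_classes``) sit on ``X[0][1..4]``.
``decode_mode`` selects a single head (L2/L3/L4) or deep supervision (DS):
training sums the loss over all four heads and inference combines the four
softmax outputs (mean by default).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "PyramidPooling",
    "AttentionGate",
    "SegmentationModel",
    "build_model",
    "forward_predict",
    "forward_logits",
    "save_checkpoint",
    "load_checkpoint",
]

DECODE_MODES = ("L2", "L3", "L4", "DS")


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 1
    num_classes: int = 6
    encoder_widths: tuple = (32, 64, 128, 256, 512)
    ppm_bins: tuple = (1, 2, 3, 6)
    ppm_enabled: bool = True
    ag_enabled: bool = True
    ag_full_grid: bool = False
    decode_mode: str = "DS"
    ds_head_combine: str = "mean"  # or "last"

    def __post_init__(self) -> None:
        if len(self.encoder_widths) != 5 or any(w <= 0 for w in self.encoder_widths):
            raise ValueError("encoder_widths must be 5 positive integers")
        if list(self.ppm_bins) != sorted(set(self.ppm_bins)):
            raise ValueError("ppm_bins must be strictly increasing")
        if self.decode_mode not in DECODE_MODES:
            raise ValueError(f"decode_mode must be one of {DECODE_MODES}")
        if self.ds_head_combine not in ("mean", "last"):
            raise ValueError("ds_head_combine must be 'mean' or 'last'")


TINY_WIDTHS = (8, 16, 32, 64, 128)  # CPU-sized preset
MICRO_WIDTHS = (4, 8, 16, 32, 64)


class PyramidPooling(nn.Module):
    """Multi-scale context aggregation on one feature map.

    Output spatial size equals the input's; output channels are exactly
    ``2 × in_channels`` (input plus N branches of ``in_channels / N``).
    """

    def __init__(self, in_ch: int, bins: tuple, rng: np.random.Generator):
        super().__init__()
        self.bins = tuple(bins)
        n = len(self.bins)
        red = max(1, in_ch // n)
        self.out_channels = in_ch + n * red
        for k, _b in enumerate(self.bins):
            setattr(self, f"reduce{k}", nn.Conv2d(in_ch, red, 1, rng, bias=False))
            setattr(self, f"bn{k}", nn.BatchNorm2d(red))

    def forward(self, x: Tensor) -> Tensor:
        _, h, w, _ = x.data.shape
        if max(self.bins) > min(h, w):
            raise ValueError(
                f"ppm bin {max(self.bins)} exceeds feature size {(h, w)}"
            )
        feats = [x]
        for k, b in enumerate(self.bins):
            p = nn.adaptive_avg_pool(x, (b, b))
            p = nn.relu(getattr(self, f"bn{k}")(getattr(self, f"reduce{k}")(p)))
            feats.append(nn.bilinear_resize(p, (h, w)))
        return nn.concat(feats, axis=-1)


class AttentionGate(nn.Module):
    """Additive attention producing a (0,1) coefficient that scales ``feat``.

    ``signal`` (the deeper decoder feature) and ``feat`` (the skip bundle)
    each pass a 1×1 conv + BN; the signal path is resampled to ``feat``'s
    size; the sum goes through ReLU, a second 1×1 conv + BN, and a sigmoid.
    """

    def __init__(self, signal_ch: int, feat_ch: int, rng: np.random.Generator,
                 inter_ch: int | None = None):
        super().__init__()
        inter = inter_ch if inter_ch is not None else max(1, feat_ch // 2)
        self.conv_sig = nn.Conv2d(signal_ch, inter, 1, rng, bias=False)
        self.bn_sig = nn.BatchNorm2d(inter)
        self.conv_feat = nn.Conv2d(feat_ch, inter, 1, rng, bias=False)
        self.bn_feat = nn.BatchNorm2d(inter)
        self.conv_psi = nn.Conv2d(inter, 1, 1, rng, bias=True)
        self.bn_psi = nn.BatchNorm2d(1)

    def coefficient(self, signal: Tensor, feat: Tensor) -> Tensor:
        _, h, w, _ = feat.data.shape
        s = self.bn_sig(self.conv_sig(signal))
        s = nn.bilinear_resize(s, (h, w))
        f = self.bn_feat(self.conv_feat(feat))
        q = nn.relu(s + f)
        return nn.sigmoid(self.bn_psi(self.conv_psi(q)))

    def forward(self, signal: Tensor, feat: Tensor) -> Tensor:
        return feat * self.coefficient(signal, feat)


def attention_gate(gate: AttentionGate, enc: Tensor, dec: Tensor) -> Tensor:
    """Functional form: gate ``dec`` with a coefficient computed from both."""
    return gate(enc, dec)


class _Up(nn.Module):
    """Bilinear ×2 followed by a channel-preserving 1×1 conv."""

    def __init__(self, ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(ch, ch, 1, rng, bias=True)

    def forward(self, x: Tensor, out_hw: tuple[int, int]) -> Tensor:
        return self.conv(nn.bilinear_resize(x, out_hw))


class SegmentationModel(nn.Module):
    """The full grid; see module docstring."""

    DEPTH = 5

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        w = cfg.encoder_widths
        # encoder column
        for i in range(self.DEPTH):
            in_ch = cfg.in_channels if i == 0 else w[i - 1]
            setattr(self, f"enc{i}", nn.ConvBlock(in_ch, w[i], rng))
        if cfg.ppm_enabled:
            self.ppm = PyramidPooling(w[4], cfg.ppm_bins, rng)
            self.ppm_fuse = nn.Conv2d(self.ppm.out_channels, w[4], 3, rng, bias=False)
            self.ppm_bn = nn.BatchNorm2d(w[4])
        # decoder grid
        for j in range(1, self.DEPTH):
            for i in range(0, self.DEPTH - j):
                setattr(self, f"up{i}_{j}", _Up(w[i + 1], rng))
                in_ch = j * w[i] + w[i + 1]
                setattr(self, f"node{i}_{j}", nn.ConvBlock(in_ch, w[i], rng))
                if cfg.ag_enabled and (i == 0 or cfg.ag_full_grid):
                    setattr(
                        self,
                        f"ag{i}_{j}",
                        AttentionGate(signal_ch=w[i + 1], feat_ch=j * w[i], rng=rng),
                    )
        # heads on X[0][1..4]
        for j in range(1, self.DEPTH):
            setattr(self, f"head{j}", nn.Conv2d(w[0], cfg.num_classes, 1, rng, bias=True))

    # -- forward -------------------------------------------------------------
    def _max_column(self) -> int:
        return {"L2": 2, "L3": 3, "L4": 4, "DS": 4}[self.cfg.decode_mode]

    def forward(self, x: Tensor) -> list[Tensor]:
        """Return head logits: all four in DS mode, one otherwise."""
        if x.data.ndim != 4 or x.data.shape[-1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (B, H, W, {self.cfg.in_channels}) input, got {x.data.shape}"
            )
        jmax = self._max_column()
        grid: dict[tuple[int, int], Tensor] = {}
        cur = x
        for i in range(self.DEPTH):
            if i > 0:
                cur = nn.maxpool2x2(cur)
            cur = getattr(self, f"enc{i}")(cur)
            grid[(i, 0)] = cur
        if self.cfg.ppm_enabled:
            p = self.ppm(grid[(4, 0)])
            grid[(4, 0)] = nn.relu(self.ppm_bn(self.ppm_fuse(p)))
        for j in range(1, jmax + 1):
            for i in range(0, self.DEPTH - j):
                if i + j > jmax:  # nodes not needed for the selected heads
                    continue
                deeper = grid[(i + 1, j - 1)]
                skips = [grid[(i, jj)] for jj in range(j)]
                bundle = skips[0] if len(skips) == 1 else nn.concat(skips, axis=-1)
                if hasattr(self, f"ag{i}_{j}"):
                    bundle = getattr(self, f"ag{i}_{j}")(deeper, bundle)
                hw = bundle.data.shape[1:3]
                up = getattr(self, f"up{i}_{j}")(deeper, hw)
                grid[(i, j)] = getattr(self, f"node{i}_{j}")(nn.concat([bundle, up], axis=-1))
        if self.cfg.decode_mode == "DS":
            return [getattr(self, f"head{j}")(grid[(0, j)]) for j in range(1, 5)]
        return [getattr(self, f"head{jmax}")(grid[(0, jmax)])]


def build_model(cfg: ModelConfig, seed: int = 0) -> SegmentationModel:
    """Construct a seeded model; the plain nested U-Net is recovered with
    ``ppm_enabled = ag_enabled = False``."""
    rng = np.random.default_rng(seed)
    return SegmentationModel(cfg, rng)


def _as_batch(images: np.ndarray) -> tuple[np.ndarray, bool]:
    """(H,W) | (B,H,W) | (B,H,W,1) grayscale → channels-last (B,H,W,1)."""
    images = np.asarray(images, dtype=np.float32)
    single = images.ndim == 2
    if single:
        images = images[None]
    if images.ndim == 3:
        images = images[..., None]
    return images, single


def forward_logits(model: SegmentationModel, images: np.ndarray) -> list[np.ndarray]:
    """Head logits as (B, C, H, W) arrays (one per active head)."""
    batch, _ = _as_batch(images)
    heads = model(Tensor(batch))
    return [np.ascontiguousarray(h.data.transpose(0, 3, 1, 2)) for h in heads]


def forward_predict(
    model: SegmentationModel, images: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predict (probs, labels) for a batch (or single) of grayscale images.

    probs is (B, C, H, W) with per-pixel class sums of 1; labels is the
    argmax (ties resolved toward the lower class index).  DS-mode heads are
    combined per ``ds_head_combine``.
    """
    batch, single = _as_batch(images)
    model.eval()
    heads = model(Tensor(batch))
    from .nn.losses import softmax_probs

    if model.cfg.decode_mode == "DS" and model.cfg.ds_head_combine == "mean":
        probs = np.mean([softmax_probs(h.data) for h in heads], axis=0)
    else:
        probs = softmax_probs(heads[-1].data)
    probs = probs.transpose(0, 3, 1, 2)  # (B, C, H, W)
    labels = probs.argmax(axis=1).astype(np.uint8)
    if single:
        return probs[0], labels[0]
    return probs, labels


# ---------------------------------------------------------------------------
# checkpoints: npz weights + JSON config sidecar


def save_checkpoint(model: SegmentationModel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.cfg), indent=2, sort_keys=True))
    return path


def load_checkpoint(path: str | Path) -> SegmentationModel:
    path = Path(path)
    cfg_raw = json.loads(path.with_suffix(".json").read_text())
    for key in ("encoder_widths", "ppm_bins"):
        cfg_raw[key] = tuple(cfg_raw[key])
    cfg = ModelConfig(**cfg_raw)
    model = build_model(cfg, seed=0)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
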