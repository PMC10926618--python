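"""Training losses as autodiff ops.

Wraps the pure-numpy Lovász-Softmax functions of :mod:`echoseg.lovasz` into
an op whose backward pass is the analytic subgradient: the extension's
gradient with respect to each class error vector is the ``g`` vector
scattered back through the descending-error permutation, followed by the
softmax Jacobian.
"""

from __future__ import annotations

import numpy as np

from ..lovasz import softmax_scores
from .autograd import Tensor

__all__ = ["lovasz_softmax_op", "cross_entropy_op", "softmax_probs"]


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """(..., C) channels-last logits → per-pixel probabilities over classes."""
    return softmax_scores(np.asarray(logits, dtype=np.float64), axis=-1)


def _flatten(logits: Tensor, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    C = logits.data.shape[-1]
    probs = softmax_probs(logits.data).reshape(-1, C)
    t = np.asarray(truth).reshape(-1)
    if t.shape[0] != probs.shape[0]:
        raise ValueError("truth size does not match logits")
    return probs, t


def _fast_lovasz_grad(probs32: np.ndarray, truth: np.ndarray, classes: str):
    """Single-precision loss/gradient identical in form to
    :func:`echoseg.lovasz.lovasz_softmax_grad`; the training hot path.

    Tests cross-check it against the float64 reference implementation.
    """
    C = probs32.shape[1]
    if classes == "all":
        cs = range(C)
    elif classes == "present":
        present = set(np.unique(truth)) | set(np.unique(probs32.argmax(axis=1)))
        cs = sorted(c for c in present if c < C)
    else:
        raise ValueError("classes must be 'all' or 'present'")
    cs = list(cs)
    dprobs = np.zeros_like(probs32)
    total = 0.0
    for c in cs:
        fc = probs32[:, c]
        gt = truth == c
        errors = np.where(gt, 1.0 - fc, fc).astype(np.float32)
        order = np.argsort(-errors, kind="stable")
        gts = np.float32(gt.sum())
        gs = gt[order].astype(np.float32)
        inter = gts - np.cumsum(gs, dtype=np.float32)
        union = gts + np.cumsum(1.0 - gs, dtype=np.float32)
        with np.errstate(invalid="ignore", divide="ignore"):
            jac = 1.0 - inter / union
        jac = np.where(union == 0, 0.0, jac)
        g = np.empty_like(jac)
        g[0] = jac[0]
        g[1:] = jac[1:] - jac[:-1]
        total += float(errors[order] @ g)
        de = np.empty_like(g)
        de[order] = g
        dprobs[:, c] += np.where(gt, -de, de)
    n = len(cs)
    return total / n, dprobs / n


def lovasz_softmax_op(logits: Tensor, truth: np.ndarray, classes: str = "all") -> Tensor:
    """Batch-level Lovász-Softmax loss of (B, H, W, C) logits.

    All pixels of the batch are flattened into one vector per class, so the
    surrogate targets the batch-level Jaccard index.
    """
    C = logits.data.shape[-1]
    z = logits.data.reshape(-1, C)
    z = z - z.max(axis=1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=1, keepdims=True)
    probs = z  # float32 (p, C)
    t = np.asarray(truth).reshape(-1)
    if t.shape[0] != probs.shape[0]:
        raise ValueError("truth size does not match logits")
    loss, dprobs = _fast_lovasz_grad(probs, t, classes)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite loss")
    # softmax Jacobian: dF = f ⊙ (df − Σ_c df_c f_c)
    inner = (dprobs * probs).sum(axis=1, keepdims=True)
    dlogits = (probs * (dprobs - inner)).reshape(logits.data.shape).astype(np.float32)

    def bwd(g):
        return (np.asarray(g).item() * dlogits,)

    return Tensor(np.array(loss, dtype=np.float32), parents=(logits,), backward=bwd)


def cross_entropy_op(logits: Tensor, truth: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy; optional warm-up companion loss."""
    probs, t = _flatten(logits, truth)
    p = probs[np.arange(t.size), t]
    loss = float(-np.log(np.maximum(p, 1e-12)).mean())
    onehot = np.zeros_like(probs)
    onehot[np.arange(t.size), t] = 1.0
    dlogits = ((probs - onehot) / t.size).reshape(logits.data.shape).astype(np.float32)

    def bwd(g):
        return (np.asarray(g).item() * dlogits,)

    return Tensor(np.array(loss, dtype=np.float32), parents=(logits,), backward=bwd)
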