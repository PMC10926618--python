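"""Lovász-Softmax loss: a convex surrogate for the per-class Jaccard loss.

The Jaccard (IOU) loss of a class is a submodular set function on the
hypercube of mispredicted-pixel indicator vectors.  Its Lovász extension is
the tight convex closure of that set function, so it can be minimised with
first-order methods while agreeing exactly with the discrete Jaccard loss on
binary error vectors.  Combined with softmax class probabilities this gives a
differentiable training loss that directly targets mean IOU.

Everything here operates on plain numpy arrays and is free of I/O and of any
neural-network machinery; :mod:`echoseg.nn.losses` wraps these functions into
an autodiff op for training.

Conventions
-----------
* pixels are flattened; an "image" argument may be any shape as long as
  prediction and truth match.
* probabilities are ``(p, C)`` with rows summing to 1 (see
  :func:`softmax_scores`).
* ``0/0 = 1`` for the Jaccard *index* of a class absent from both maps, i.e.
  loss 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ErrorVector",
    "jaccard_loss_discrete",
    "softmax_scores",
    "error_vector",
    "lovasz_grad",
    "lovasz_extension",
    "lovasz_softmax_loss",
]


@dataclass
class ErrorVector:
    """Per-pixel error vector ``E(c)`` of one class, plus its truth mask.

    ``values[i]`` is ``1 - f_i(c)`` where the true class is ``c`` and
    ``f_i(c)`` elsewhere; ``gt_mask[i]`` flags the pixels whose true class
    is ``c``.
    """

    values: np.ndarray
    gt_mask: np.ndarray
    class_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        self.gt_mask = np.asarray(self.gt_mask).ravel().astype(bool)
        if self.values.shape != self.gt_mask.shape:
            raise ValueError("values and gt_mask must have equal length")
        if self.values.size and (self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError("error-vector entries must lie in [0, 1]")


def jaccard_loss_discrete(pred: np.ndarray, truth: np.ndarray, c: int) -> float:
    """Discrete Jaccard loss ``1 - |P∩T| / |P∪T|`` of class ``c``.

    ``P = {pred = c}``, ``T = {truth = c}``; an empty union scores index 1
    (loss 0) by convention.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred == c
    t = truth == c
    union = np.logical_or(p, t).sum()
    if union == 0:
        return 0.0
    inter = np.logical_and(p, t).sum()
    return 1.0 - inter / union


def softmax_scores(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    """Map unnormalised scores ``F_i(c)`` to probabilities along ``axis``.

    Stabilised by max-subtraction; rejects non-finite input.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("softmax input contains NaN or infinite scores")
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2:
        raise ValueError("probs must be (pixels, classes)")
    if probs.size and not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1 within 1e-6")
    return probs


def error_vector(probs: np.ndarray, truth: np.ndarray, c: int) -> ErrorVector:
    """Pixel error vector ``E_i(c) = 1 - f_i(c)`` on class-c pixels, else ``f_i(c)``."""
    probs = _check_probs(probs)
    truth = np.asarray(truth).ravel()
    if truth.shape[0] != probs.shape[0]:
        raise ValueError("truth length must equal number of probability rows")
    fc = probs[:, c]
    gt = truth == c
    values = np.where(gt, 1.0 - fc, fc)
    return ErrorVector(values=values, gt_mask=gt, class_index=c)


def lovasz_grad(sorted_gt: np.ndarray) -> np.ndarray:
    """Gradient vector ``g`` of the Lovász extension of the Jaccard loss.

    ``sorted_gt`` is the boolean truth mask of one class permuted into the
    descending-error order π.  Entry ``g_i`` is the increase of the discrete
    Jaccard loss when pixel π_i joins the mispredicted set
    ``{π_1, …, π_{i-1}}``, computed in closed form with cumulative sums:
    after ``i`` pixels, ``intersection = |T| - cumsum(sorted_gt)_i`` and
    ``union = |T| + cumsum(1 - sorted_gt)_i``.
    """
    gt = np.asarray(sorted_gt).ravel().astype(np.float64)
    p = gt.shape[0]
    if p == 0:
        return np.zeros(0)
    gts = gt.sum()
    intersection = gts - np.cumsum(gt)
    union = gts + np.cumsum(1.0 - gt)
    with np.errstate(invalid="ignore", divide="ignore"):
        jaccard_loss = 1.0 - intersection / union
    jaccard_loss = np.where(union == 0, 0.0, jaccard_loss)  # empty class: Δ of any prefix is 0
    g = np.empty(p)
    g[0] = jaccard_loss[0]  # Δ(∅) = 0
    g[1:] = jaccard_loss[1:] - jaccard_loss[:-1]
    return g


def lovasz_extension(err: ErrorVector) -> float:
    """Lovász extension ``Σ_i E_{π_i} g_i`` of the Jaccard loss at ``E``.

    Pixels are sorted by descending error; ties broken by ascending pixel
    index (mergesort keeps the original order among equal keys).
    """
    e = err.values
    if e.size == 0:
        return 0.0
    order = np.argsort(-e, kind="stable")
    e_sorted = e[order]
    g = lovasz_grad(err.gt_mask[order])
    return float(np.dot(e_sorted, g))


def lovasz_softmax_loss(
    probs: np.ndarray,
    truth: np.ndarray,
    num_classes: int | None = None,
    classes: str = "all",
) -> float:
    """Class-averaged Lovász-Softmax loss.

    Parameters
    ----------
    probs : (p, C) array of per-pixel class probabilities.
    truth : length-p integer label vector.
    num_classes : number of classes; defaults to ``probs.shape[1]``.
    classes : ``"all"`` averages over every class (the definition);
        ``"present"`` averages only over classes occurring in truth or in
        the argmax prediction, which is less noisy on mini-batches that
        lack rare classes.
    """
    probs = _check_probs(probs)
    truth = np.asarray(truth).ravel()
    if probs.shape[0] == 0:
        raise ValueError("loss undefined on zero pixels")
    C = num_classes if num_classes is not None else probs.shape[1]
    if classes == "all":
        cs = range(C)
    elif classes == "present":
        present = set(np.unique(truth)) | set(np.unique(probs.argmax(axis=1)))
        cs = sorted(c for c in present if c < C)
    else:
        raise ValueError("classes must be 'all' or 'present'")
    losses = [lovasz_extension(error_vector(probs, truth, c)) for c in cs]
    return float(np.mean(losses))


def lovasz_softmax_grad(
    probs: np.ndarray, truth: np.ndarray, classes: str = "all"
) -> tuple[float, np.ndarray]:
    """Loss and its (sub)gradient with respect to the probabilities.

    The extension is piecewise linear in ``E``; at a fixed descending-error
    permutation its gradient w.r.t. ``E(c)`` is ``g`` scattered back through
    the permutation, and ``dE_i/df_i(c)`` is ``-1`` on class-c pixels and
    ``+1`` elsewhere.  At sort ties this is a valid subgradient.
    """
    probs = _check_probs(probs)
    truth = np.asarray(truth).ravel()
    C = probs.shape[1]
    if classes == "all":
        cs = list(range(C))
    elif classes == "present":
        present = set(np.unique(truth)) | set(np.unique(probs.argmax(axis=1)))
        cs = sorted(c for c in present if c < C)
    else:
        raise ValueError("classes must be 'all' or 'present'")
    dprobs = np.zeros_like(probs)
    total = 0.0
    for c in cs:
        err = error_vector(probs, truth, c)
        e = err.values
        order = np.argsort(-e, kind="stable")
        g = lovasz_grad(err.gt_mask[order])
        total += float(np.dot(e[order], g))
        de = np.empty_like(e)
        de[order] = g
        sign = np.where(err.gt_mask, -1.0, 1.0)
        dprobs[:, c] += sign * de
    n = len(cs)
    return total / n, dprobs / n
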