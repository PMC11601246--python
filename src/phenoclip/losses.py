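"""Training losses.

Three terms drive training: a focal-weighted symmetric contrastive (CLIP)
loss aligning [CLS] cell embeddings with cell-type name embeddings; a
label-smoothed binary cross-entropy aligning attention-derived marker
positivity scores with gated positivity labels; and a label-smoothed
cross-entropy on the gradient-reversed modality head whose weight ramps
with the quartic root of the epoch index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, softmax

__all__ = ["LossWeights", "focal_clip_loss", "positivity_loss",
           "modality_loss", "adversarial_weight", "total_loss"]

EPS = 1e-8


@dataclass
class LossWeights:
    w_cls: float = 1.0
    w_pos: float = 1.0
    w_adv_base: float = 0.1
    ramp_exponent: float = 0.25
    epochs_total: int = 20

    def __post_init__(self):
        if min(self.w_cls, self.w_pos, self.w_adv_base) < 0:
            raise ValueError("loss weights must be non-negative")


def _normalize_rows(x: Tensor) -> Tensor:
    norm = ((x * x).sum(axis=-1, keepdims=True) + EPS) ** 0.5
    return x / norm


def _focal_nll(p: Tensor, gamma: float) -> Tensor:
    """Mean of (1 - p_t)^gamma * (-log p_t) over the diagonal targets."""
    n = p.shape[0]
    idx = np.arange(n)
    pt = p[idx, idx].clip(EPS, 1.0)
    ce = -pt.log()
    if gamma == 0:
        return ce.mean()
    return ((1.0 - pt) ** gamma * ce).mean()


def focal_clip_loss(image_embs: Tensor | np.ndarray, text_embs: Tensor | np.ndarray,
                    gamma: float = 2.0, tau: Tensor | float = 0.07) -> Tensor:
    """Symmetric focal CLIP loss over matched (image, text) embedding rows.

    Rows are L2-normalized, the similarity matrix S = I T^T / tau is
    softmaxed along rows (image view) and along rows of S^T (text view), and
    each view contributes a focal negative log-likelihood on the diagonal
    targets; the two views are averaged. Differentiable in I, T, and tau.
    """
    image_embs = as_tensor(image_embs)
    text_embs = as_tensor(text_embs)
    tau = as_tensor(tau)
    if image_embs.shape != text_embs.shape:
        raise ValueError("image and text embeddings must have matching shape")
    if np.any(tau.data <= 0):
        raise ValueError("tau must be positive")
    i_n = _normalize_rows(image_embs)
    t_n = _normalize_rows(text_embs)
    s = (i_n @ t_n.transpose(1, 0)) / tau
    p_img = softmax(s, axis=-1)
    p_txt = softmax(s.transpose(1, 0), axis=-1)
    return (_focal_nll(p_img, gamma) + _focal_nll(p_txt, gamma)) * 0.5


def positivity_loss(scores: Tensor | np.ndarray, targets: np.ndarray,
                    padding_mask: np.ndarray, smoothing: float = 0.2,
                    label_mask: np.ndarray | None = None) -> Tensor:
    """Label-smoothed BCE between positivity scores and gated labels.

    Binary targets t are smoothed to t (1 - s) + s/2. The mean is taken over
    real channels that carry a positivity label; if none do, returns zero.
    """
    scores = as_tensor(scores)
    valid = np.asarray(padding_mask, dtype=np.float64).copy()
    if label_mask is not None:
        valid *= np.asarray(label_mask, dtype=np.float64)
    n_valid = valid.sum()
    if n_valid == 0:
        import warnings

        warnings.warn("no labeled channels in batch; positivity loss is 0")
        return as_tensor(np.zeros((), dtype=scores.dtype))
    t = np.asarray(targets, dtype=np.float64) * (1.0 - smoothing) + smoothing / 2.0
    p = scores.clip(1e-6, 1.0 - 1e-6)  # float32-safe clamp
    bce = -(t * p.log() + (1.0 - t) * (1.0 - p).log())
    return (bce * valid).sum() / n_valid


def modality_loss(logits: Tensor, targets: np.ndarray, smoothing: float = 0.01) -> Tensor:
    """Cross-entropy with uniformly redistributed label smoothing."""
    logits = as_tensor(logits)
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=np.float64)
    onehot[np.arange(n), np.asarray(targets, dtype=int)] = 1.0
    smoothed = onehot * (1.0 - smoothing) + smoothing / k
    logp = softmax(logits, axis=-1).clip(EPS, 1.0).log()
    return -(logp * smoothed).sum(axis=-1).mean()


def adversarial_weight(epoch: int, w_adv_base: float, ramp_exponent: float = 0.25) -> float:
    """Ramped adversary weight: w_adv_base * epoch^(1/4), with epoch 0 -> 0.

    ``epoch`` is the 1-based index of the current epoch (0 means the ramp
    has not started).
    """
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return w_adv_base * float(epoch) ** ramp_exponent


def total_loss(loss_cls: Tensor, loss_pos: Tensor, loss_adv: Tensor | None,
               weights: LossWeights, epoch: int):
    """Weighted sum of the three terms plus a per-term breakdown."""
    w_adv = adversarial_weight(epoch, weights.w_adv_base, weights.ramp_exponent)
    total = weights.w_cls * loss_cls + weights.w_pos * loss_pos
    breakdown = {"loss_cls": float(loss_cls.data), "loss_pos": float(loss_pos.data),
                 "w_adv": w_adv}
    if loss_adv is not None:
        total = total + w_adv * loss_adv
        breakdown["loss_adv"] = float(loss_adv.data)
    breakdown["loss_total"] = float(total.data)
    for name in ("loss_cls", "loss_pos", "loss_adv"):
        if name in breakdown and not np.isfinite(breakdown[name]):
            raise FloatingPointError(f"non-finite value in {name}")
    return total, breakdown
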