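"""Training recipe: focal loss on smoothed targets, AdamW, cosine warm
restarts, early stopping, and stratified splitting.

Defaults mirror the reference training configuration: batch 32, up to 50
epochs with early stopping at patience 5 on validation loss, AdamW at
initial learning rate 1e-3 with weight decay 1e-4, focal loss (α = 0.25,
γ = 2) on label-smoothed targets (ε = 0.1), and cosine annealing with warm
restarts (T₀ = 10 epochs, T_mult = 2 — common SGDR defaults, since only the
scheduler family is prescribed).

The focal/smoothing composition applies smoothing to the target first and
then the focal modulation per class:

    loss = −Σ_k α · (1 − p_k)^γ · q_k · log(p_k)

which reduces to plain label-smoothed cross-entropy at γ = 0, α = 1 and to
the standard focal loss at ε = 0.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np

from ._nn import AdamW, Model, softmax_stable
from .imaging_io import (AugmentConfig, ImageDataset, augment, channel_stats,
                         normalize)

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-12  # floor inside log for numerical safety
_IMPROVE_EPS = 1e-6  # strict-improvement margin for early stopping

__all__ = ["TrainConfig", "smooth_labels", "focal_loss", "cosine_lr",
           "early_stop", "stratified_split", "train"]


@dataclass
class TrainConfig:
    """Validated training configuration; defaults are the reference recipe."""

    batch_size: int = 32
    max_epochs: int = 50
    lr0: float = 0.001
    weight_decay: float = 1e-4
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    label_smoothing: float = 0.1
    patience: int = 5
    restart_period: int = 10
    restart_mult: int = 2
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.patience,
               self.restart_period, self.restart_mult) < 1:
            raise ValueError("batch/epochs/patience/restart settings must be >= 1")
        if not (0 <= self.label_smoothing < 1):
            raise ValueError("label smoothing must lie in [0, 1)")
        if self.lr0 <= 0 or self.focal_alpha <= 0 or self.focal_gamma < 0:
            raise ValueError("need lr0 > 0, focal_alpha > 0, focal_gamma >= 0")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must lie in (0, 1)")


def smooth_labels(class_index: int, num_classes: int, epsilon: float) -> np.ndarray:
    """q = (1−ε)·onehot + ε/K; the mass floor per class is ε/K."""
    if not 0 <= class_index < num_classes:
        raise ValueError("class index out of range")
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must lie in [0, 1)")
    q = np.full(num_classes, epsilon / num_classes)
    q[class_index] += 1.0 - epsilon
    return q


def focal_loss(probs: np.ndarray, q: np.ndarray, alpha: float, gamma: float) -> float:
    """Focal loss on smoothed targets; batch inputs reduce by mean.

    ``probs`` and ``q`` are (K,) or (N, K) probability vectors. Probabilities
    are floored at 1e-12 inside the log.
    """
    p = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    t = np.atleast_2d(np.asarray(q, dtype=np.float64))
    if p.shape != t.shape:
        raise ValueError("probs and targets must have matching shapes")
    logs = np.log(np.maximum(p, _LOG_FLOOR))
    per = -(alpha * (1.0 - p) ** gamma * t * logs).sum(axis=1)
    return float(per.mean())


def _focal_from_logits(logits: np.ndarray, q: np.ndarray, alpha: float,
                       gamma: float) -> tuple[float, np.ndarray]:
    """Mean focal loss and its gradient w.r.t. the logits."""
    p = softmax_stable(logits, axis=1)
    pf = np.maximum(p, _LOG_FLOOR)
    logp = np.log(pf)
    one_m = 1.0 - p
    loss = float((-(alpha * one_m ** gamma * q * logp).sum(axis=1)).mean())
    # dL/dp_k, then pull back through the softmax Jacobian
    if gamma == 0:
        dldp = -alpha * q / pf
    else:
        dldp = alpha * q * (gamma * one_m ** (gamma - 1.0) * logp - one_m ** gamma / pf)
    inner = (p * dldp).sum(axis=1, keepdims=True)
    dlogits = p * (dldp - inner) / logits.shape[0]
    return loss, dlogits


def cosine_lr(t: int, cfg: TrainConfig) -> float:
    """Cosine annealing with warm restarts, epoch granularity, lr_min = 0.

    Within a cycle of length Tᵢ: lr = ½·lr0·(1 + cos(π·t_cur/Tᵢ)); at each
    restart t_cur resets and Tᵢ ← Tᵢ·T_mult.
    """
    if t < 0:
        raise ValueError("epoch index must be >= 0")
    t_cur, ti = t, cfg.restart_period
    while t_cur >= ti:
        t_cur -= ti
        ti *= cfg.restart_mult
    return 0.5 * cfg.lr0 * (1.0 + np.cos(np.pi * t_cur / ti))


def early_stop(val_losses, patience: int) -> int | None:
    """1-based epoch after which training stops, or None if it never does.

    Stops after the first epoch at which no strict improvement (> 1e-6)
    over the running best has occurred for ``patience`` consecutive epochs.
    """
    if patience < 1:
        raise ValueError("patience must be >= 1")
    best = np.inf
    stale = 0
    for i, v in enumerate(val_losses, start=1):
        if v < best - _IMPROVE_EPS:
            best = v
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                return i
    return None


def stratified_split(labels, test_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-class largest-remainder split into (train, test) index arrays.

    Disjoint, exhaustive, reproducible by seed; per-class test proportions
    deviate from the global fraction by less than one sample.
    """
    labels = np.asarray(labels)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members")
    exact = counts * test_fraction
    base = np.floor(exact).astype(int)
    total_test = int(round(len(labels) * test_fraction))
    remainder = exact - base
    extra = total_test - base.sum()
    order = np.argsort(-remainder, kind="stable")
    take = base.copy()
    for idx in order[:max(extra, 0)]:
        take[idx] += 1
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls, n_test in zip(classes, take):
        members = np.flatnonzero(labels == cls)
        perm = rng.permutation(members)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    return (np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx)))


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _eval_pass(model: Model, images: np.ndarray, q: np.ndarray, labels: np.ndarray,
               cfg: TrainConfig, batch_size: int = 64) -> tuple[float, float]:
    losses, hits, total = [], 0, 0
    for start in range(0, len(images), batch_size):
        xb = images[start:start + batch_size].transpose(0, 3, 1, 2)
        logits = model.forward(xb, train=False)
        p = softmax_stable(logits, axis=1)
        losses.append(focal_loss(p, q[start:start + batch_size],
                                 cfg.focal_alpha, cfg.focal_gamma) * len(xb))
        hits += int((logits.argmax(axis=1) == labels[start:start + batch_size]).sum())
        total += len(xb)
    return sum(losses) / total, hits / total


def train(model: Model, dataset: ImageDataset, cfg: TrainConfig,
          augment_cfg: AugmentConfig | None = None,
          ) -> tuple[Model, list[dict]]:
    """Train in place; returns (model with best-validation weights, history).

    A stratified validation carve-out (``cfg.val_fraction`` of the provided
    data) monitors early stopping; channel statistics are computed on the
    training portion only and applied everywhere. History rows carry epoch
    (1-based), lr, train/val loss and accuracy.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if augment_cfg is None:
        augment_cfg = AugmentConfig.light()
    k = len(dataset.class_names)
    rng = np.random.default_rng(cfg.seed)
    tr_idx, val_idx = stratified_split(dataset.labels, cfg.val_fraction, cfg.seed + 1)
    train_set, val_set = dataset.subset(tr_idx), dataset.subset(val_idx)
    mean, std = channel_stats(train_set)
    smooth = np.stack([smooth_labels(c, k, cfg.label_smoothing) for c in range(k)])
    val_images = normalize(val_set.images, mean, std)
    val_q = smooth[val_set.labels]

    opt = AdamW(model, lr=cfg.lr0, weight_decay=cfg.weight_decay)
    history: list[dict] = []
    best_loss, best_state, stale = np.inf, None, 0
    for epoch in range(cfg.max_epochs):
        lr = cosine_lr(epoch, cfg)
        opt.lr = lr
        ep_loss, ep_hits, ep_n = 0.0, 0, 0
        for batch in _iter_batches(len(train_set), cfg.batch_size, rng):
            raw = train_set.images[batch]
            if augment_cfg.enabled:
                raw = np.stack([augment(im, augment_cfg, rng) for im in raw])
            xb = normalize(raw, mean, std).transpose(0, 3, 1, 2)
            yb = train_set.labels[batch]
            logits = model.forward(xb, train=True)
            loss, dlogits = _focal_from_logits(
                logits, smooth[yb], cfg.focal_alpha, cfg.focal_gamma)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1}; "
                    "check learning rate and input scaling")
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * len(batch)
            ep_hits += int((logits.argmax(axis=1) == yb).sum())
            ep_n += len(batch)
        val_loss, val_acc = _eval_pass(model, val_images, val_q, val_set.labels, cfg)
        row = {"epoch": epoch + 1, "lr": float(lr),
               "train_loss": ep_loss / ep_n, "train_acc": ep_hits / ep_n,
               "val_loss": val_loss, "val_acc": val_acc}
        history.append(row)
        logger.info("epoch %(epoch)d lr=%(lr).2e train_loss=%(train_loss).4f "
                    "train_acc=%(train_acc).3f val_loss=%(val_loss).4f "
                    "val_acc=%(val_acc).3f", row)
        if val_loss < best_loss - _IMPROVE_EPS:
            best_loss, stale = val_loss, 0
            best_state = copy.deepcopy(model.state_dict())
        else:
            stale += 1
            if stale >= cfg.patience:
                logger.info("early stopping after epoch %d", epoch + 1)
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model._train_stats = (mean, std)  # normalization stats travel with the model
    return model, history
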