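"""Training protocol and evaluation.

Networks train with Adam on shuffled mini-batches (batch 32, up to 20
epochs by default).  At the end of each epoch the parameters are snapshotted
only if the absolute difference between the epoch's average training error
and validation error is smaller than after all previous epochs (an
early-save rule that limits over-training); ties keep the earliest epoch.
The snapshot with the smallest gap is restored when training ends.  The
epoch's training error is the running mean of the training loss (the
standard per-epoch fit metric); batch-norm inference statistics are
recalibrated on training data before each validation evaluation.  The
learning-rate schedule front-loads convergence (decay steps early in the
epoch budget) so that the epochs among which the rule selects are trained
to their plateau.

Position networks are scored as the mean Euclidean distance between
prediction and ground truth in native (unscaled) full-frame pixels on the
validation regions, excluding gross errors above 7.5 native px, which are
reported separately as a rate; the gross-error filter is applied only in
evaluation, never in training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .layers import F32, Adam
from .network import Network, input_to_native, native_to_input

__all__ = ["TrainProtocol", "train_network", "evaluate_position_net",
           "evaluate_classifier", "DivergenceError", "regions_to_arrays",
           "GROSS_ERROR_PX"]

GROSS_ERROR_PX = 7.5


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class TrainProtocol:
    batch_size: int = 32
    epochs: int = 20
    learning_rate: float = 1e-3
    # step decay: multiply the learning rate by `decay_factor` when the
    # epoch index crosses each fraction in `decay_at` (polishes the
    # sub-pixel precision of the soft-argmax heads)
    decay_at: Tuple[float, ...] = (0.25, 0.5, 0.75)
    decay_factor: float = 0.3
    # clip the global gradient norm: occasional outlier batches otherwise
    # cause transient validation spikes that destabilize epoch selection
    max_grad_norm: float = 300.0
    seed: int = 0
    com_one_hot: bool = False  # alternative one-hot training of the CoM head

    def lr_at(self, epoch: int) -> float:
        lr = self.learning_rate
        for frac in self.decay_at:
            if epoch >= frac * self.epochs:
                lr *= self.decay_factor
        return lr


def regions_to_arrays(regions: Sequence, feature: str = "pupil"
                      ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LabeledRegions -> (images (N,S,S), native targets (N,2), offsets (N,2)).

    ``feature`` is "pupil", "glint_a", "glint_b" or "class"; for "class" the
    second array holds binary valid labels instead of positions.
    """
    images = np.stack([r.image for r in regions]).astype(F32)
    offsets = np.stack([np.asarray(r.crop_offset, float) for r in regions])
    if feature == "class":
        labels = np.array([1 if r.valid else 0 for r in regions])
        return images, labels, offsets
    targets = np.stack([np.asarray(getattr(r, feature), float) for r in regions])
    return images, targets, offsets


def _epoch_error(net: Network, x: np.ndarray, target: np.ndarray,
                 batch: int = 256) -> float:
    """Mean per-sample error in eval mode: cross-entropy for the classifier,
    Euclidean distance in input px for position heads."""
    total = 0.0
    n = x.shape[0]
    for i in range(0, n, batch):
        xb = x[i:i + batch]
        out = net.forward(xb, train=False)
        if net.cfg.head == "classifier":
            p = np.clip(out[np.arange(len(xb)), target[i:i + batch].astype(int)],
                        1e-7, 1.0)
            total += float(-np.log(p).sum())
        else:
            total += float(np.sqrt(((out - target[i:i + batch]) ** 2)
                                   .sum(axis=1)).sum())
    return total / n


def train_network(net: Network, train_images: np.ndarray, train_targets: np.ndarray,
                  val_images: np.ndarray, val_targets: np.ndarray,
                  proto: Optional[TrainProtocol] = None,
                  ) -> List[Dict[str, float]]:
    """Train in place; returns the per-epoch history.

    Images are native crops (N, S, S); the network's own down-scaling is
    applied here.  Position targets must already be expressed in the head's
    down-scaled input coordinates (see :func:`native_to_input`); classifier
    targets are binary labels.
    """
    proto = proto or TrainProtocol()
    rng = np.random.default_rng(proto.seed)
    x = net.downscale_images(train_images)
    xv = net.downscale_images(val_images)
    t = np.asarray(train_targets)
    tv = np.asarray(val_targets)

    opt = Adam(net.params, net.grads, lr=proto.learning_rate)
    history: List[Dict[str, float]] = []
    best_gap = np.inf
    best_state = None
    n = x.shape[0]
    for epoch in range(proto.epochs):
        opt.lr = proto.lr_at(epoch)
        order = rng.permutation(n)
        run_loss, run_n = 0.0, 0
        for i in range(0, n, proto.batch_size):
            idx = order[i:i + proto.batch_size]
            opt.zero_grad()
            loss = net.loss_and_backward(x[idx], t[idx],
                                         com_one_hot=proto.com_one_hot)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            if proto.max_grad_norm:
                gn = np.sqrt(sum(float((g ** 2).sum()) for g in net.grads))
                if gn > proto.max_grad_norm:
                    scale = F32(proto.max_grad_norm / gn)
                    for g in net.grads:
                        g *= scale
            opt.step()
            run_loss += loss
            run_n += len(idx)
        # refresh batch-norm inference statistics before evaluating: the
        # running estimates lag the weights and a late outlier batch would
        # otherwise skew the validation error and destabilize the rule
        net.recalibrate_bn(x)
        train_err = run_loss / run_n
        val_err = _epoch_error(net, xv, tv)
        gap = abs(train_err - val_err)
        saved = gap < best_gap
        if saved:
            best_gap = gap
            best_state = net.state_dict()
        history.append({"epoch": epoch, "train_err": train_err,
                        "val_err": val_err, "train_loss": run_loss / run_n,
                        "saved": float(saved)})
    if best_state is not None:
        net.load_state_dict(best_state)
    return history


def saved_epoch(history: Sequence[Dict[str, float]]) -> int:
    """Index of the epoch whose snapshot the early-save rule retains."""
    gaps = [abs(h["train_err"] - h["val_err"]) for h in history]
    best, arg = np.inf, 0
    for i, g in enumerate(gaps):
        if g < best:
            best, arg = g, i
    return arg


def predict_native(net: Network, images: np.ndarray, offsets: np.ndarray,
                   batch: int = 256) -> np.ndarray:
    """Position predictions mapped back to native full-frame pixels."""
    x = net.downscale_images(images)
    preds = []
    for i in range(0, x.shape[0], batch):
        preds.append(net.forward(x[i:i + batch], train=False))
    pred_input = np.concatenate(preds, axis=0)
    return input_to_native(pred_input, offsets, net.cfg.downscale)


def evaluate_position_net(net: Network, images: np.ndarray,
                          targets_native: np.ndarray, offsets: np.ndarray
                          ) -> Tuple[float, float]:
    """(mean error in native px excluding gross errors > 7.5 px, gross rate)."""
    pred = predict_native(net, images, offsets)
    err = np.sqrt(((pred - targets_native) ** 2).sum(axis=1))
    gross = err > GROSS_ERROR_PX
    rate = float(gross.mean())
    kept = err[~gross]
    mean_err = float(kept.mean()) if kept.size else 0.0
    return mean_err, rate


def evaluate_classifier(net: Network, images: np.ndarray, labels: np.ndarray,
                        threshold: float = 0.5, batch: int = 256) -> float:
    """Classification accuracy at a valid-probability threshold (default 0.5)."""
    x = net.downscale_images(images)
    correct = 0
    for i in range(0, x.shape[0], batch):
        p_valid = net.forward(x[i:i + batch], train=False)[:, 1]
        pred = (p_valid > threshold).astype(int)
        correct += int((pred == labels[i:i + batch]).sum())
    return correct / len(labels)
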