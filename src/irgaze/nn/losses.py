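"""The two training objectives of the feature extractor.

Both are batch sums, not means: binary cross-entropy over valid/invalid
class probabilities for the classifier, and summed Euclidean distances for
the position estimators.
"""

from __future__ import annotations

import numpy as np

__all__ = ["classifier_loss", "regression_loss"]

_EPS = 1e-7  # probability clamp: the loss diverges at p in {0, 1}


def classifier_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Binary cross-entropy  sum_i -(y_i log p_i + (1-y_i) log(1-p_i)).

    ``p`` is the predicted probability that a region is a valid eye region,
    ``y`` the binary class label.  Probabilities are clamped to
    [1e-7, 1 - 1e-7] before the logarithm.
    """
    p = np.asarray(p, float)
    y = np.asarray(y, float)
    if p.shape != y.shape:
        raise ValueError("p and y must have equal shapes")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def regression_loss(pred: np.ndarray, gt: np.ndarray) -> float:
    """Summed Euclidean distance  sum_i sqrt((x_i-gtx_i)^2 + (y_i-gty_i)^2)."""
    pred = np.asarray(pred, float)
    gt = np.asarray(gt, float)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt must have equal shapes")
    return float(np.sqrt(((pred - gt) ** 2).sum(axis=-1)).sum())
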