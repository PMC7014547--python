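"""Network assembly: base architecture plus one of three output heads.

* ``classifier`` -- two softmax neurons giving P(invalid), P(valid).
* ``regression`` -- two linear neurons predicting the feature location
  relative to the input crop ([0.5, 0.5] = center).
* ``center_of_mass`` -- one neuron per input pixel, softmax over the map,
  then a differentiable 2D center-of-mass (soft-argmax) whose expectation
  over pixel-center coordinates is the sub-pixel position estimate.  The
  position loss is back-propagated through the expectation, so the network
  is trained end-to-end with the same Euclidean objective as the plain
  regression head; an optional one-hot cross-entropy mode treats the
  nearest pixel as a class target instead.

Positions at the head operate in down-scaled input pixels; helpers map
between those and native full-frame pixels via the crop offset and scale.
"""

from __future__ import annotations

import copy
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import NetConfig, InvalidConfigError
from .layers import (F32, BatchNorm2d, Conv2d, Dense, Dropout, Flatten,
                     Layer, MaxPool2x2, ReLU, softmax)

__all__ = ["Network", "build_network", "center_of_mass",
           "input_to_native", "native_to_input"]


def center_of_mass(p: np.ndarray) -> np.ndarray:
    """Probability-weighted mean pixel coordinate of probability map(s).

    ``p`` is (H, W) or (N, H, W), non-negative and normalized to sum 1 per
    map; coordinates are pixel centers (x right, y down, 0-based).  The
    result always lies inside the convex hull of the map, i.e. the input
    bounds.
    """
    p = np.asarray(p, float)
    single = p.ndim == 2
    if single:
        p = p[None]
    sums = p.sum(axis=(1, 2))
    if np.any(p < -1e-9) or np.any(np.abs(sums - 1) > 1e-6):
        raise ValueError("probability maps must be non-negative and sum to 1")
    h, w = p.shape[1:]
    xs = np.arange(w, dtype=float)
    ys = np.arange(h, dtype=float)
    cx = (p.sum(axis=1) * xs).sum(axis=1)
    cy = (p.sum(axis=2) * ys).sum(axis=1)
    out = np.stack([cx, cy], axis=1)
    return out[0] if single else out


def input_to_native(xy: np.ndarray, crop_offset: np.ndarray, downscale: int) -> np.ndarray:
    """Down-scaled input coordinates -> native full-frame pixels.

    Down-scaled pixel ``j`` is the block mean of native pixels
    ``j*d .. j*d+d-1``, whose center is ``j*d + (d-1)/2``.
    """
    xy = np.asarray(xy, float)
    return xy * downscale + (downscale - 1) / 2.0 + np.asarray(crop_offset, float)


def native_to_input(xy_native: np.ndarray, crop_offset: np.ndarray, downscale: int) -> np.ndarray:
    xy = np.asarray(xy_native, float) - np.asarray(crop_offset, float)
    return (xy - (downscale - 1) / 2.0) / downscale


class Network:
    """A configured base architecture with head, ready for training."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        cfg.validate(strict_ranges=False)
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        s = cfg.net_input
        self.layers: List[Layer] = []
        cin = 1
        for spec in cfg.conv_layers:
            self.layers.append(Conv2d(cin, spec.n_kernels, spec.kernel_width,
                                      self.rng, needs_input_grad=cin != 1))
            if spec.batch_norm:
                self.layers.append(BatchNorm2d(spec.n_kernels))
            self.layers.append(ReLU())
            if spec.pooling_2x2:
                self.layers.append(MaxPool2x2())
                s //= 2
            cin = spec.n_kernels
        self.layers.append(Flatten())
        feat = cin * s * s
        for n in cfg.dense_layers:
            self.layers.append(Dense(feat, n, self.rng))
            self.layers.append(ReLU())
            feat = n
        if cfg.dense_layers:
            self.layers.append(Dropout(cfg.dropout, self.rng))
        self.head_dense = Dense(feat, cfg.head_width(), self.rng)
        self.layers.append(self.head_dense)

    # -- plumbing ----------------------------------------------------------
    @property
    def params(self) -> List[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> List[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {f"p{i}": p.copy() for i, p in enumerate(self.params)}
        for i, l in enumerate(self.layers):
            if isinstance(l, BatchNorm2d):
                out[f"bn{i}_mean"] = l.run_mean.copy()
                out[f"bn{i}_var"] = l.run_var.copy()
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            p[...] = state[f"p{i}"]
        for i, l in enumerate(self.layers):
            if isinstance(l, BatchNorm2d):
                l.run_mean[...] = state[f"bn{i}_mean"]
                l.run_var[...] = state[f"bn{i}_var"]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))

    def downscale_images(self, images: np.ndarray) -> np.ndarray:
        """(N, S, S) native crops -> (N, s, s, 1) network inputs (NHWC).

        Block-mean down-scaling followed by per-image standardization
        (zero mean, unit variance), which removes the large illumination
        and gain variation between captures.
        """
        d = self.cfg.downscale
        n, h, w = images.shape
        if d > 1:
            images = images.reshape(n, h // d, d, w // d, d).mean(axis=(2, 4))
        images = images.astype(F32)
        mu = images.mean(axis=(1, 2), keepdims=True)
        sd = images.std(axis=(1, 2), keepdims=True)
        images = (images - mu) / np.maximum(sd, 1e-4)
        return images[..., None]

    def recalibrate_bn(self, x: np.ndarray, batch: int = 256,
                       max_samples: int = 640) -> None:
        """Recompute exact batch-norm inference statistics on ``x``.

        During training the running statistics lag the weights and a single
        outlier batch can skew them right before evaluation; refreshing
        them over a training subsample gives stable, reproducible
        inference behavior (standard BN recalibration).  No-op without
        batch-norm layers.
        """
        bns = [l for l in self.layers if isinstance(l, BatchNorm2d)]
        if not bns:
            return
        for l in bns:
            l.begin_collect()
        n = min(len(x), max_samples)
        for i in range(0, n, batch):
            self._forward_raw(x[i:i + batch], train=False)
        for l in bns:
            l.end_collect()

    # -- forward / loss ----------------------------------------------------
    def _forward_raw(self, x: np.ndarray, train: bool) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Head output: class probabilities (N, 2) for the classifier, or
        positions (N, 2) in down-scaled input px for position heads."""
        z = self._forward_raw(x, train)
        s = self.cfg.net_input
        if self.cfg.head == "classifier":
            return softmax(z)
        if self.cfg.head == "regression":
            return z * (s - 1)  # relative -> input px
        p = softmax(z)
        self._probs = p if train else None
        return center_of_mass(p.reshape(-1, s, s))

    def prob_map(self, x: np.ndarray) -> np.ndarray:
        """(N, s, s) softmax probability maps (center-of-mass head only)."""
        if self.cfg.head != "center_of_mass":
            raise InvalidConfigError("probability maps require the center-of-mass head")
        z = self._forward_raw(x, False)
        s = self.cfg.net_input
        return softmax(z).reshape(-1, s, s)

    def loss_and_backward(self, x: np.ndarray, target: np.ndarray,
                          com_one_hot: bool = False) -> float:
        """One training step's loss (summed over the batch, matching the
        published loss definitions) and parameter-gradient accumulation.

        Targets: int class labels (classifier) or positions in down-scaled
        input px (position heads).
        """
        n = x.shape[0]
        s = self.cfg.net_input
        z = self._forward_raw(x, True)
        if self.cfg.head == "classifier":
            p = softmax(z)
            y = np.asarray(target).astype(int)
            eps = 1e-7
            loss = float(-np.log(np.clip(p[np.arange(n), y], eps, 1.0)).sum())
            dz = p.copy()
            dz[np.arange(n), y] -= 1.0
        elif self.cfg.head == "regression":
            pred = z * (s - 1)
            diff = pred - target
            dist = np.sqrt((diff ** 2).sum(axis=1))
            loss = float(dist.sum())
            dpred = diff / np.maximum(dist, 1e-12)[:, None]
            dz = dpred * (s - 1)
        else:
            p = softmax(z)
            if com_one_hot:
                # alternative mode: nearest pixel as a classification target
                tx = np.clip(np.round(target[:, 0]), 0, s - 1).astype(int)
                ty = np.clip(np.round(target[:, 1]), 0, s - 1).astype(int)
                idx = ty * s + tx
                eps = 1e-7
                loss = float(-np.log(np.clip(p[np.arange(n), idx], eps, 1.0)).sum())
                dz = p.copy()
                dz[np.arange(n), idx] -= 1.0
            else:
                pred = center_of_mass(p.reshape(-1, s, s))
                diff = pred - target
                dist = np.sqrt((diff ** 2).sum(axis=1))
                loss = float(dist.sum())
                dpred = diff / np.maximum(dist, 1e-12)[:, None]
                xs = np.arange(s, dtype=F32)
                grid = np.stack(np.meshgrid(xs, xs, indexing="xy"), axis=-1)
                gcoord = grid.reshape(-1, 2)  # (s*s, 2): (x, y) per neuron
                dp = dpred @ gcoord.T  # (N, s*s)
                dz = p * (dp - (p * dp).sum(axis=1, keepdims=True))
        dz = dz.astype(F32)
        g = dz
        for l in reversed(self.layers):
            g = l.backward(g)
        return loss

    def clone(self) -> "Network":
        net = Network(copy.deepcopy(self.cfg), seed=0)
        net.load_state_dict(self.state_dict())
        return net


def build_network(cfg: NetConfig, seed: int = 0, strict_ranges: bool = True) -> Network:
    """Validate a configuration against the hyperparameter space (ranges,
    spatial feasibility, training-memory cap) and instantiate it."""
    cfg.validate(strict_ranges=strict_ranges)
    return Network(cfg, seed=seed)
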