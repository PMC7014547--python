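"""Random architecture sampling and Pareto accuracy-vs-cost analysis."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import (DOWNSCALE_CHOICES, DOWNSCALE_CHOICES_COARSE,
                     DROPOUT_CHOICES, KERNEL_CHOICES, N_CONV_CHOICES,
                     N_DENSE_CHOICES, NEURON_CHOICES, WIDTH_CHOICES,
                     ConvSpec, InvalidConfigError, NetConfig)

__all__ = ["random_configs", "pareto_front"]


def _sample_config(rng: np.random.Generator, input_size: int, head: str,
                   allow_downscale_8: bool) -> NetConfig:
    ds_choices = DOWNSCALE_CHOICES_COARSE if allow_downscale_8 else DOWNSCALE_CHOICES
    ds = int(rng.choice([d for d in ds_choices if input_size % d == 0]))
    n_conv = int(rng.choice(N_CONV_CHOICES))
    convs = [ConvSpec(n_kernels=int(rng.choice(KERNEL_CHOICES)),
                      kernel_width=int(rng.choice(WIDTH_CHOICES)),
                      pooling_2x2=bool(rng.integers(0, 2)),
                      batch_norm=True)
             for _ in range(n_conv)]
    n_dense = int(rng.choice(N_DENSE_CHOICES))
    dense = [int(rng.choice(NEURON_CHOICES)) for _ in range(n_dense)]
    return NetConfig(input_size=input_size, downscale=ds, conv_layers=convs,
                     dense_layers=dense, dropout=float(rng.choice(DROPOUT_CHOICES)),
                     head=head)


def random_configs(n: int, seed: int = 0, input_size: int = 64,
                   head: str = "center_of_mass",
                   allow_downscale_8: bool = False) -> List[NetConfig]:
    """Draw ``n`` base-architecture configurations uniformly from the
    hyperparameter ranges; infeasible draws (pooling below 1 px, memory cap)
    are discarded and resampled, so exactly ``n`` valid configs return."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: List[NetConfig] = []
    while len(out) < n:
        cfg = _sample_config(rng, input_size, head, allow_downscale_8)
        try:
            cfg.validate()
        except InvalidConfigError:
            continue
        out.append(cfg)
    return out


def pareto_front(points: Sequence[Tuple[float, float]]) -> List[Tuple[float, float]]:
    """Non-dominated subset of (error, cost) points.

    A point is dominated when another point has error <= and cost <= with at
    least one strict inequality.  Exact duplicates collapse to one entry;
    among points of equal error only the lowest cost survives.  The front is
    returned sorted by increasing error.
    """
    pts = [(float(e), float(c)) for e, c in points]
    if not pts:
        return []
    if not all(np.isfinite(v) for p in pts for v in p):
        raise ValueError("points must be finite")
    uniq = sorted(set(pts))
    front: List[Tuple[float, float]] = []
    best_cost = np.inf
    last_err: Optional[float] = None
    for e, c in uniq:  # sorted by error then cost
        if e == last_err:
            continue  # equal error: the first (lowest cost) already kept
        if c < best_cost:
            front.append((e, c))
            best_cost = c
        last_err = e
    return front
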