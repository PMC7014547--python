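"""Deterministic per-inference operation counting.

Convention (documented, fixed): a multiply-accumulate is 2 flops; conv and
dense layers count MACs x 2 plus one add per output for the bias; batch
norm costs 2 flops per element at inference (fused scale + shift); 2x2 max
pooling costs 3 comparisons per output; softmax ~3 flops per element; the
center-of-mass expectation ~4 flops per map element.  Reference mflops for
the published selected networks were produced by a framework's internal
counter under an unknown convention, so they are treated as reference
points rather than exact targets.
"""

from __future__ import annotations

from .config import NetConfig

__all__ = ["count_mflops"]


def count_mflops(cfg: NetConfig) -> float:
    """Millions of floating-point operations for one forward inference."""
    flops = 0
    maps = cfg.feature_maps()
    cin, size = maps[0]
    for spec, (cout, out_size) in zip(cfg.conv_layers, maps[1:]):
        k = spec.kernel_width
        px = size * size  # same padding: conv output keeps the input size
        flops += 2 * k * k * cin * cout * px + cout * px
        if spec.batch_norm:
            flops += 2 * cout * px
        flops += cout * px  # relu
        if spec.pooling_2x2:
            flops += 3 * cout * out_size * out_size
        cin, size = cout, out_size
    feat = cin * size * size
    for n in cfg.dense_layers:
        flops += 2 * feat * n + n + n  # matmul + bias + relu
        feat = n
    width = cfg.head_width()
    flops += 2 * feat * width + width
    if cfg.head == "classifier":
        flops += 3 * width
    elif cfg.head == "center_of_mass":
        flops += 3 * width + 4 * width
    return flops / 1e6
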