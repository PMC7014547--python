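"""The six-network coarse-to-fine feature-extraction cascade.

Two cheap, aggressively down-scaled pupil localizers (256-px crop at 8x and
128-px crop at 4x) successively tighten the eye region from an initial
proposal (the previous frame's pupil, or an externally supplied eye-region
center on cold start).  A 64-px crop is then cut at the refined estimate; a
classifier gates it as a valid eye region at probability threshold 0.5, and
if valid three precise estimators (pupil at full resolution, the two
corneal reflections at 2x) produce sub-pixel positions in full-frame
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from ..geometry import EyeFeatures
from .config import ConvSpec, NetConfig
from .network import Network, input_to_native

__all__ = ["CascadeConfig", "FeatureExtractor", "default_cascade_config",
           "selected_net_configs"]

NET_ROLES = ("pupil_coarse", "pupil_medium", "classifier",
             "pupil_fine", "cr_a", "cr_b")


def selected_net_configs() -> Dict[str, NetConfig]:
    """The six selected architectures.

    The five position networks follow the published selections (kernel
    counts/widths per conv layer, one hidden dense layer, dropout; pooling
    and batch norm on every conv layer).  The classifier's exact
    architecture was not published beyond its 64-px crop, no down-scaling
    and ~20 mflops cost; the configuration here is drawn from the same
    hyperparameter space and reproduces that cost.
    """
    def conv(k, w):
        return ConvSpec(n_kernels=k, kernel_width=w, pooling_2x2=True,
                        batch_norm=True)

    return {
        # p1: coarse pupil localizer, 256 crop at 8x
        "pupil_coarse": NetConfig(
            input_size=256, downscale=8,
            conv_layers=[conv(24, 4), conv(2, 3), conv(16, 5)],
            dense_layers=[512], dropout=0.7, head="center_of_mass"),
        # p2: medium localizer, 128 crop at 4x
        "pupil_medium": NetConfig(
            input_size=128, downscale=4,
            conv_layers=[conv(24, 4), conv(2, 3), conv(16, 5)],
            dense_layers=[1024], dropout=0.7, head="center_of_mass"),
        "classifier": NetConfig(
            input_size=64, downscale=1,
            conv_layers=[conv(16, 5), conv(16, 5), conv(16, 5)],
            dense_layers=[64], dropout=0.5, head="classifier"),
        # p3: fine pupil estimator, 64 crop at full resolution
        "pupil_fine": NetConfig(
            input_size=64, downscale=1,
            conv_layers=[conv(8, 4), conv(32, 6), conv(8, 3), conv(32, 6)],
            dense_layers=[1024], dropout=0.7, head="center_of_mass"),
        "cr_a": NetConfig(
            input_size=64, downscale=2,
            conv_layers=[conv(64, 5), conv(8, 3), conv(64, 5)],
            dense_layers=[1024], dropout=0.5, head="center_of_mass"),
        "cr_b": NetConfig(
            input_size=64, downscale=2,
            conv_layers=[conv(16, 4), conv(48, 3), conv(48, 6)],
            dense_layers=[1024], dropout=0.4, head="center_of_mass"),
    }


@dataclass
class CascadeConfig:
    nets: Dict[str, NetConfig]
    validity_threshold: float = 0.5

    def __post_init__(self) -> None:
        missing = set(NET_ROLES) - set(self.nets)
        if missing:
            raise ValueError(f"cascade missing networks: {sorted(missing)}")
        expected = {"pupil_coarse": (256, 8), "pupil_medium": (128, 4),
                    "classifier": (64, 1), "pupil_fine": (64, 1),
                    "cr_a": (64, 2), "cr_b": (64, 2)}
        for role, (crop, ds) in expected.items():
            cfg = self.nets[role]
            if (cfg.input_size, cfg.downscale) != (crop, ds):
                raise ValueError(
                    f"{role}: expected crop {crop} at {ds}x, got "
                    f"{cfg.input_size} at {cfg.downscale}x")


def default_cascade_config() -> CascadeConfig:
    return CascadeConfig(nets=selected_net_configs())


class ProposalOutsideFrameError(ValueError):
    pass


def _cut_crop(frame: np.ndarray, center: np.ndarray, size: int
              ) -> Tuple[np.ndarray, np.ndarray]:
    """Cut a size x size crop centered near ``center`` (frame px), clamped
    into the frame; returns (crop, offset of its top-left pixel)."""
    h, w = frame.shape
    ox = int(round(center[0] - (size - 1) / 2.0))
    oy = int(round(center[1] - (size - 1) / 2.0))
    ox = min(max(ox, 0), w - size)
    oy = min(max(oy, 0), h - size)
    return frame[oy:oy + size, ox:ox + size], np.array([ox, oy], float)


class FeatureExtractor:
    """Trained cascade networks bound to a cascade configuration."""

    def __init__(self, config: CascadeConfig, networks: Dict[str, Network]):
        missing = set(NET_ROLES) - set(networks)
        if missing:
            raise ValueError(f"missing trained networks: {sorted(missing)}")
        self.config = config
        self.nets = networks

    def _position(self, role: str, frame: np.ndarray, center: np.ndarray
                  ) -> np.ndarray:
        net = self.nets[role]
        crop, off = _cut_crop(frame, center, net.cfg.input_size)
        x = net.downscale_images(crop[None])
        pred = net.forward(x, train=False)[0]
        return input_to_native(pred, off, net.cfg.downscale)

    def extract(self, frame: np.ndarray, proposal: np.ndarray,
                frame_offset: Tuple[float, float] = (0.0, 0.0)) -> EyeFeatures:
        """Run the cascade on a grayscale frame.

        ``proposal`` is the region-proposal point in full-frame px (previous
        pupil estimate or an external eye-region center); ``frame_offset``
        locates ``frame``'s top-left pixel in full-frame coordinates when
        the frame is itself a sub-window.  Returns features in full-frame
        px, or ``valid=False`` when the classifier rejects the region.
        """
        frame = np.asarray(frame, np.float32)
        h, w = frame.shape
        prop = np.asarray(proposal, float) - np.asarray(frame_offset, float)
        if not (0 <= prop[0] < w and 0 <= prop[1] < h):
            raise ProposalOutsideFrameError("proposal outside the frame")
        if h < 256 or w < 256:
            raise ValueError("frame smaller than the coarse crop (256 px)")

        p = self._position("pupil_coarse", frame, prop)
        p = self._position("pupil_medium", frame, p)

        clf = self.nets["classifier"]
        crop, off = _cut_crop(frame, p, clf.cfg.input_size)
        p_valid = clf.forward(clf.downscale_images(crop[None]), train=False)[0, 1]
        shift = np.asarray(frame_offset, float)
        if p_valid <= self.config.validity_threshold:
            return EyeFeatures(None, None, None, False)

        pupil = self._position("pupil_fine", frame, p)
        ga = self._position("cr_a", frame, p)
        gb = self._position("cr_b", frame, p)
        return EyeFeatures(pupil + shift, ga + shift, gb + shift, True)
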