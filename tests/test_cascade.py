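"""Coarse-to-fine cascade: localization accuracy, gating, end-to-end run."""

import numpy as np
import pytest

from irgaze.nn import (ConvSpec, NetConfig, Network, CascadeConfig,
                       FeatureExtractor, default_cascade_config,
                       selected_net_configs)
from irgaze.nn.cascade import ProposalOutsideFrameError
from irgaze.nn.network import native_to_input
from irgaze.nn.train import (TrainProtocol, evaluate_position_net,
                             regions_to_arrays, train_network)
from irgaze.synth import RenderConfig, generate_dataset

LOC_SEED = 21


def train_position(ds, cfg, feature, epochs, seed=LOC_SEED, valid_only=False):
    tr = ds.subset("train", valid_only=valid_only)
    va = ds.subset("val", valid_only=valid_only)
    if feature != "pupil":
        tr = [r for r in tr if getattr(r, feature) is not None]
        va = [r for r in va if getattr(r, feature) is not None]
    xi, ti, oi = regions_to_arrays(tr, feature)
    xv, tv, ov = regions_to_arrays(va, feature)
    net = Network(cfg, seed=seed)
    train_network(net, xi, native_to_input(ti, oi, cfg.downscale),
                  xv, native_to_input(tv, ov, cfg.downscale),
                  TrainProtocol(epochs=epochs, seed=seed))
    return net, (xv, tv, ov)


@pytest.fixture(scope="module")
def ds256():
    return generate_dataset(10, 16, cfg=RenderConfig(crop_size=256),
                            n_aug=4, seed=LOC_SEED)


@pytest.fixture(scope="module")
def ds128():
    return generate_dataset(10, 16, cfg=RenderConfig(crop_size=128),
                            n_aug=4, seed=LOC_SEED + 1)


@pytest.fixture(scope="module")
def coarse_net(ds256):
    cfg = selected_net_configs()["pupil_coarse"]
    net, val = train_position(ds256, cfg, "pupil", epochs=12)
    return net, val


@pytest.fixture(scope="module")
def medium_net(ds128):
    cfg = selected_net_configs()["pupil_medium"]
    net, val = train_position(ds128, cfg, "pupil", epochs=12)
    return net, val


@pytest.fixture(scope="module")
def extractor(coarse_net, medium_net, trained_classifier, trained_pupil_fine,
              trained_cr_a, benchmark_dataset_session):
    cfg_b = selected_net_configs()["cr_b"]
    cr_b, _ = train_position(benchmark_dataset_session, cfg_b, "glint_b",
                             epochs=4, valid_only=True)
    nets = {
        "pupil_coarse": coarse_net[0],
        "pupil_medium": medium_net[0],
        "classifier": trained_classifier["net"],
        "pupil_fine": trained_pupil_fine["net"],
        "cr_a": trained_cr_a["net"],
        "cr_b": cr_b,
    }
    return FeatureExtractor(default_cascade_config(), nets)


class TestCascadeConfig:
    def test_default_crop_downscale_pairs(self):
        cc = default_cascade_config()
        assert cc.validity_threshold == 0.5
        assert (cc.nets["pupil_coarse"].input_size,
                cc.nets["pupil_coarse"].downscale) == (256, 8)
        assert (cc.nets["pupil_fine"].input_size,
                cc.nets["pupil_fine"].downscale) == (64, 1)

    def test_wrong_pairing_rejected(self):
        nets = selected_net_configs()
        nets["pupil_coarse"] = nets["pupil_fine"]
        with pytest.raises(ValueError):
            CascadeConfig(nets=nets)


class TestLocalizers:
    def test_coarse_plus_medium_localize_within_6px_per_axis(
            self, coarse_net, medium_net, ds256):
        # the two-stage hierarchy must center the 64-px crop well enough
        # that the pupil and both glints are never clipped
        from irgaze.nn.cascade import _cut_crop
        from irgaze.nn.network import input_to_native
        coarse, medium = coarse_net[0], medium_net[0]
        errs = []
        for s in ds256.subset("val"):
            x = coarse.downscale_images(s.image[None])
            p1 = input_to_native(coarse.forward(x)[0], s.crop_offset, 8)
            crop, off = _cut_crop(s.image, p1 - s.crop_offset, 128)
            x2 = medium.downscale_images(crop[None])
            p2 = input_to_native(medium.forward(x2)[0],
                                 off + s.crop_offset, 4)
            errs.append(np.abs(p2 - s.pupil))
        errs = np.array(errs)
        frac = (errs <= 6.0).all(axis=1).mean()
        assert frac >= 0.9
        assert np.median(errs) < 3.0

    def test_medium_refines_below_coarse(self, coarse_net, medium_net):
        _, err_c = evaluate_wrap(coarse_net)
        _, err_m = evaluate_wrap(medium_net)
        assert err_m < err_c


def evaluate_wrap(fixture):
    net, (xv, tv, ov) = fixture
    err, gross = evaluate_position_net(net, xv, tv, ov)
    return gross, err


class TestExtractFeatures:
    def make_frames(self, n, seed, leds_on=(True, True)):
        cfg = RenderConfig(crop_size=256, sensor_noise_sd=(0.003, 0.006),
                           blur_kernel_px=(0.0, 0.2),
                           eyelid_occlusion_fraction=(0.0, 0.0))
        ds = generate_dataset(4, n, cfg=cfg, n_aug=1, p_blink=0.0,
                              p_heavy_blur=0.0, seed=seed)
        return [s for s in ds.samples if s.valid] if leds_on == (True, True) \
            else ds.samples

    def test_end_to_end_on_clean_regions(self, extractor):
        # cold-start proposals up to 20 px off: the cascade must accept the
        # clean regions and localize all three features at sub-pixel median
        # accuracy (raw errors, no gross-error filtering)
        frames = self.make_frames(12, seed=31)
        rng = np.random.default_rng(32)
        assert len(frames) > 25
        total = 0
        pupil_errs, glint_errs = [], []
        for s in frames:
            proposal = s.pupil + rng.uniform(-20, 20, 2)
            f = extractor.extract(s.image, proposal, frame_offset=s.crop_offset)
            if not f.valid:
                continue
            total += 1
            pupil_errs.append(np.linalg.norm(f.pupil - s.pupil))
            glint_errs.append(np.linalg.norm(f.glint_a - s.glint_a))
            glint_errs.append(np.linalg.norm(f.glint_b - s.glint_b))
        pupil_errs = np.array(pupil_errs)
        glint_errs = np.array(glint_errs)
        assert total >= 0.9 * len(frames)  # classifier accepts clean regions
        assert np.median(pupil_errs) <= 0.8
        assert (pupil_errs <= 1.0).mean() >= 0.75
        assert (pupil_errs <= 1.5).mean() >= 0.85
        assert np.median(glint_errs) <= 0.8
        assert (glint_errs <= 1.5).mean() >= 0.9

    def test_led_disabled_region_gated_invalid(self, extractor):
        cfg = RenderConfig(crop_size=256)
        ds = generate_dataset(3, 12, cfg=cfg, n_aug=1, p_blink=0.0,
                              p_heavy_blur=0.0, seed=33)
        rng = np.random.default_rng(34)
        missing = [s for s in ds.samples if (s.glint_a is None) or
                   (s.glint_b is None)]
        assert missing
        rejected = 0
        for s in missing:
            f = extractor.extract(s.image, s.pupil + rng.uniform(-10, 10, 2),
                                  frame_offset=s.crop_offset)
            if not f.valid:
                rejected += 1
                assert f.pupil is None and f.glint_a is None
        assert rejected / len(missing) >= 0.9

    def test_proposal_outside_frame_rejected(self, extractor):
        frame = np.zeros((256, 256), np.float32)
        with pytest.raises(ProposalOutsideFrameError):
            extractor.extract(frame, np.array([500.0, 10.0]))


class TestSmallerCropAdvantage:
    def test_64_crop_beats_256_crop_at_matched_mflops(self, ds256,
                                                      benchmark_dataset_session):
        # identical architecture and input resolution (64 px maps): the
        # 256-crop network sees the same pixels 4x coarser
        def arch(input_size, downscale):
            return NetConfig(input_size=input_size, downscale=downscale,
                             conv_layers=[ConvSpec(8, 3, True, True),
                                          ConvSpec(8, 3, True, True)],
                             dense_layers=[128], dropout=0.3,
                             head="center_of_mass")

        from irgaze.nn import count_mflops
        cfg64, cfg256 = arch(64, 1), arch(256, 4)
        assert count_mflops(cfg64) == pytest.approx(count_mflops(cfg256))

        sub64 = subset_n(benchmark_dataset_session, 1500)
        net64, val64 = train_position(sub64, cfg64, "pupil", epochs=3,
                                      valid_only=True)
        net256, val256 = train_position(ds256, cfg256, "pupil", epochs=3)
        err64, _ = evaluate_position_net(net64, *val64)
        err256, _ = evaluate_position_net(net256, *val256)
        assert err64 <= err256


def subset_n(ds, n):
    """A shallow dataset view with at most n training samples (speed)."""
    import copy
    out = copy.copy(ds)
    train = ds.subset("train")[:n]
    val = ds.subset("val")[:max(300, n // 4)]
    out.samples = train + val
    return out
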