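"""Train a small center-of-mass pupil estimator on synthetic eye regions.

Uses a compact architecture (not the full selected network) so the example
finishes in about a minute: the soft-argmax head reaches sub-pixel accuracy
even at this scale.  The printed history shows the early-save rule at work:
the epoch with the smallest |train - val| gap is the one kept.
"""

from irgaze.nn import ConvSpec, NetConfig, Network, count_mflops
from irgaze.nn.network import native_to_input
from irgaze.nn.train import (TrainProtocol, evaluate_position_net,
                             regions_to_arrays, train_network)
from irgaze.synth import generate_dataset

ds = generate_dataset(8, 20, seed=1)
train = ds.subset("train", valid_only=True)
val = ds.subset("val", valid_only=True)
print(f"{len(train)} training / {len(val)} validation valid 64 px regions")

cfg = NetConfig(input_size=64, downscale=2,
                conv_layers=[ConvSpec(8, 3, True, True),
                             ConvSpec(16, 3, True, True)],
                dense_layers=[256], dropout=0.3, head="center_of_mass")
print(f"architecture cost: {count_mflops(cfg):.2f} mflops per inference")

xi, ti, oi = regions_to_arrays(train, "pupil")
xv, tv, ov = regions_to_arrays(val, "pupil")
net = Network(cfg, seed=0)
history = train_network(net, xi, native_to_input(ti, oi, 2),
                        xv, native_to_input(tv, ov, 2),
                        TrainProtocol(epochs=6, seed=0))

for h in history:
    print(f"epoch {int(h['epoch'])}: train {h['train_err']:.3f} "
          f"val {h['val_err']:.3f} (input px)"
          + ("  <- snapshot kept" if h["saved"] else ""))

err, gross = evaluate_position_net(net, xv, tv, ov)
print(f"\nvalidation mean error: {err:.3f} native px "
      f"(gross-error rate {gross:.3f} at the 7.5 px cutoff)")
print("The probability-map center of mass interpolates between pixels, so"
      "\nthe error approaches the pixel scale even through the 2x"
      "\ndown-scaled input; the full selected architectures trained by the"
      "\nbenchmarks reach ~0.5 px.")
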