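"""Render a small labeled synthetic IR eye-region dataset.

Generates eye regions from the 3D forward model (two eyes per frame,
device poses at 200-400 mm, a random ~30% of frames with IR LEDs disabled,
blinks and motion blur), renders them with exact sub-pixel ground truth,
and prints the dataset statistics a real handheld collection would show:
roughly 55/45 valid/invalid and a subject-disjoint 80/20 split.
"""

from irgaze import generate_dataset

ds = generate_dataset(n_subjects=10, frames_per_subject=20, seed=0)

n = len(ds.samples)
n_valid = sum(s.valid for s in ds.samples)
print(f"base eye regions : {ds.n_base_regions} "
      f"(10 subjects x 20 frames x 2 eyes)")
print(f"after augmentation: {n} crops (10 random-offset crops per region)")
print(f"valid fraction    : {100 * n_valid / n:.1f}% "
      f"(target ~55% valid / 45% invalid)")
print(f"train subjects    : {ds.train_subjects}")
print(f"val subjects      : {ds.val_subjects}")

s = next(r for r in ds.samples if r.valid)
rel = s.pupil - s.crop_offset
print(f"\nexample valid region (subject {s.subject}):")
print(f"  crop offset (full-frame px): {s.crop_offset}")
print(f"  pupil at ({rel[0]:.2f}, {rel[1]:.2f}) within the 64 px crop")
print(f"  glints  : {s.glint_a - s.crop_offset} and {s.glint_b - s.crop_offset}")
print("  ground truth is exact sub-pixel (no click quantization)")

# ds.write_manifest("scratch/dataset", write_images=True)  # PNG + JSONL + CSV
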