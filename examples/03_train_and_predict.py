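"""Train the lightweight U-Net on synthetic patches and predict a held-out map.

A deliberately small run (eight images, ~1500 patches, two epochs; a few
minutes on a laptop CPU) under the controlled desk-scale conditions described
in docs/methods.md, so the printed numbers actually show learning.  Scale
n_per_image, max_epochs and the canonical side up for real experiments.
"""

from pathlib import Path

import lasermark as lm
from lasermark import pipeline
from lasermark.lwunet import TrainConfig

SIDE = 128
out = Path("example_output/train_demo")
cfg = lm.SynthConfig(
    seed=7, n_images=8, pattern="prp", train_fraction=6 / 8,
    size_range=(SIDE, SIDE), n_laser_marks_range=(18, 26),
    laser_radius_range=(3, 4), vessel_count=3, hue_profile="reddish",
    mark_contrast=1.5, noise_sd=2.0, camera_variation=3.0,
    max_place_attempts=2000,
)
manifest = lm.generate_dataset(cfg, out)

train_samples = pipeline.load_split_samples(manifest, "train")
test_samples = pipeline.load_split_samples(manifest, "test")
stats = pipeline.fit_stats(train_samples, SIDE)
pool = pipeline.build_patch_pool(train_samples, stats, n_per_image=250, seed=0)
print(f"patch pool: {len(pool)} windows of 48x48x3")

ckpt = lm.train(pool, TrainConfig(seed=0, max_epochs=2, lr_init=0.03))
for row in ckpt.training_log:
    print(" ", row)

sample = test_samples[0]
pmap = pipeline.predict_map(sample, ckpt, stats, stride=8)
canonical = lm.resize_to_canonical(sample, SIDE)
inside = pmap.values[canonical.lesion_mask == 1]
outside = pmap.values[canonical.lesion_mask == 0]
print(f"held-out {sample.id}: mean probability on true marks "
      f"{inside.mean():.3f} vs background {outside.mean():.3f}")
print("the gap between the two means is the scar signal the patch network "
      "has picked up after this brief run")

ckpt.save("example_output/model.npz")
lm.save_probability_map(pmap, "example_output/prediction.png")
print("saved model to example_output/model.npz and the map to "
      "example_output/prediction.png (+ lossless .npy sidecar)")
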