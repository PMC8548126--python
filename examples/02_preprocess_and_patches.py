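"""Photometric normalization and patch augmentation.

Shows the per-channel chain (resize, train-set Z-score, per-image min-max,
CLAHE + gamma, rescale to [0,1]) and the random 48-px patch extraction with
black-patch exclusion that feeds network training.
"""

from pathlib import Path

import numpy as np

import lasermark as lm
from lasermark import pipeline

out = Path("example_output/dataset")
if not (out / "manifest.csv").exists():
    cfg = lm.SynthConfig(seed=42, n_images=6, pattern="mixed",
                         size_range=(140, 180), n_laser_marks_range=(18, 26),
                         laser_radius_range=(3, 4), train_fraction=4 / 6)
    lm.generate_dataset(cfg, out)
manifest = lm.load_manifest(out / "manifest.csv")

SIDE = 128  # canonical side for this example (production default is 512)
train_samples = pipeline.load_split_samples(manifest, "train")
stats = pipeline.fit_stats(train_samples, SIDE)
print(f"fitted per-pixel stats on {stats.n_images} train images "
      f"({stats.side}x{stats.side}x3 mean/SD grids)")

sample = train_samples[0]
pre = lm.preprocess_image(sample, stats)
print(f"preprocessed {sample.id}: values in "
      f"[{pre.values.min():.3f}, {pre.values.max():.3f}] (must be within [0,1])")

# standardized training images have mean ~0 and SD ~1 at every informative pixel
zs = np.stack([
    lm.standardize(lm.resize_to_canonical(s, SIDE).image.astype(float), stats)
    for s in train_samples
])
informative = stats.sigma > 0
print(f"post-standardization over the train set: |mean| <= "
      f"{np.abs(zs.mean(0)[informative]).max():.2e}, "
      f"|SD - 1| <= {np.abs(zs.std(0)[informative] - 1).max():.2e}")

canonical = lm.resize_to_canonical(sample, SIDE)
patches = lm.extract_random_patches(pre.values, canonical.lesion_mask,
                                    n=200, window=48, rng_seed=0)
frac = patches.labels.mean()
print(f"extracted {len(patches)} random 48x48 patches; "
      f"{100 * frac:.1f}% of patch pixels are laser-mark pixels")
print("every accepted patch has image content (all-black windows are excluded)")
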