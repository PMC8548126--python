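"""Generate a small synthetic fundus dataset and inspect its ground truth.

Each sample is a color fundus photograph with a circular field of view, an
optic disc, a macula, vessels, and scattered laser-burn scars, plus exact
pixel masks for the scars and the disc.
"""

from pathlib import Path

import numpy as np

import lasermark as lm

out = Path("example_output/dataset")
cfg = lm.SynthConfig(
    seed=42,
    n_images=6,
    pattern="mixed",            # PRP / partial / untreated mix
    size_range=(140, 180),      # native pixel sizes before canonical resizing
    n_laser_marks_range=(18, 26),
    laser_radius_range=(3, 4),
    train_fraction=4 / 6,
)
manifest = lm.generate_dataset(cfg, out)

print(f"wrote {len(manifest)} samples to {out}")
for record in manifest.records:
    sample = lm.load_sample(record)
    n_lesion = int(sample.lesion_mask.sum())
    pattern = record.extras["pattern"]
    print(f"  {sample.id}: {sample.image.shape[0]}px, split={sample.split}, "
          f"pattern={pattern}, lesion pixels={n_lesion}, "
          f"macula at {tuple(round(x) for x in sample.macula_center)}")

# The lesion and optic-disc masks are disjoint by construction: burns are
# never placed on the disc.
sample = lm.load_sample(manifest.records[0])
assert not np.any(sample.lesion_mask & sample.od_mask)
print("lesion and OD masks are disjoint, as clinical practice requires")
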