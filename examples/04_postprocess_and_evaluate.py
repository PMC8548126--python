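"""Anatomy-aware postprocessing and the four-variant evaluation report.

Builds a toy probability map whose only false positives sit on the optic
disc and the macula, then shows how the two clinical masks remove them and
how the report (AUC, Youden-optimal operating point, Dice) improves.
"""

import numpy as np

from lasermark.anatomy import AnatomyFit, OdEllipse
from lasermark.fundus_io import ProbabilityMap
from lasermark.metrics import evaluate_run
from lasermark.pipeline import variant_maps

# ground truth: four laser marks in the periphery of a 200x200 image
truth = np.zeros((200, 200), np.uint8)
for r, c in [(40, 40), (40, 160), (160, 40), (160, 160)]:
    truth[r - 3 : r + 3, c - 3 : c + 3] = 1

# prediction: correct marks, plus spurious blobs on the disc and the macula
# that score even higher than the real marks (the classic bright-lesion trap)
values = np.where(truth, 0.92, 0.03).astype(float)
values[95:110, 150:165] = 0.97   # optic-disc false positive
values[95:105, 95:105] = 0.94    # macular false positive
raw = ProbabilityMap(values, id="toy")

anatomy = AnatomyFit(
    od_ellipse=OdEllipse(center_row=102, center_col=157,
                         semi_axis_x=14, semi_axis_y=14),
    od_extent=(16.0, 16.0),
    macula_center=(100.0, 100.0),
    microns_per_pixel=1800.0 / 16.0,
)

variants = variant_maps([raw], [anatomy], macula_side=30)
report = evaluate_run(variants, [truth])
print(report.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print("reading the table: the raw variant pays for the disc/macula blobs in "
      "specificity and AUC; masking either zone removes its false positives; "
      "masking both recovers a perfect ranking (AUC 1.0) because the only "
      "remaining high probabilities are the true marks")
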