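"""Rule-based panretinal photocoagulation (PRP) diagnosis from a lesion map.

PRP scatters hundreds of burns across the peripheral retina while sparing
the optic disc (no burns within 500 microns nasally) and the macula (no
burns within 3000 microns of its center).  The classifier binarizes a
postprocessed probability map, labels 8-connected components, discards tiny
components and components violating the spatial exclusion rules, and calls
the image PRP when enough marks survive and they cover enough macula-centered
quadrants.  The count and coverage thresholds are clinical reconstructions
exposed in :class:`PrpConfig`, not values fitted to data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.measure import label as cc_label, regionprops

from .anatomy import AnatomyFit
from .fundus_io import ProbabilityMap


class ClassificationError(ValueError):
    pass


@dataclass
class PrpConfig:
    threshold: float = 0.5
    min_area: int = 10  # pixels; smaller components are noise
    min_marks: int = 30
    min_quadrants: int = 3
    od_margin_microns: float = 500.0
    macula_margin_microns: float = 3000.0


@dataclass
class PrpDecision:
    is_prp: bool
    n_marks: int
    quadrant_counts: tuple[int, int, int, int]
    violations: list[tuple[int, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _od_violation(centroid, anatomy: AnatomyFit, margin_um: float) -> bool:
    """Centroid inside the OD ellipse, or within ``margin_um`` of its boundary
    on the nasal side (the side of the OD away from the macula)."""
    ell = anatomy.od_ellipse
    a, b = ell.semi_axis_x, ell.semi_axis_y
    dr = centroid[0] - ell.center_row
    dc = centroid[1] - ell.center_col
    rho = np.hypot(dc / a, dr / b) if a > 0 and b > 0 else np.inf
    if rho <= 1.0:
        return True
    nasal_dir = np.sign(ell.center_col - anatomy.macula_center[1])
    on_nasal_side = np.sign(dc) == nasal_dir and nasal_dir != 0
    if not on_nasal_side:
        return False
    # approximate distance to the ellipse boundary along the centroid ray
    boundary_dist_px = (rho - 1.0) * (a + b) / 2.0
    return boundary_dist_px * anatomy.microns_per_pixel < margin_um


def classify_prp(
    pmap: ProbabilityMap,
    anatomy: AnatomyFit,
    config: PrpConfig = PrpConfig(),
) -> PrpDecision:
    """Classify one (postprocessed) laser-mark map as PRP or not."""
    if anatomy is None:
        raise ClassificationError("anatomy fit required for PRP classification")
    binary = pmap.values >= config.threshold
    labels = cc_label(binary, connectivity=2)
    mac_r, mac_c = anatomy.macula_center
    quadrant_counts = [0, 0, 0, 0]
    violations: list[tuple[int, str]] = []
    n_marks = 0
    for prop in regionprops(labels):
        if prop.area < config.min_area:
            continue
        centroid = prop.centroid
        if _od_violation(centroid, anatomy, config.od_margin_microns):
            violations.append((int(prop.label), "od_proximity"))
            continue
        dist_um = np.hypot(centroid[0] - mac_r, centroid[1] - mac_c) * anatomy.microns_per_pixel
        if dist_um < config.macula_margin_microns:
            violations.append((int(prop.label), "macula_proximity"))
            continue
        n_marks += 1
        quad = (0 if centroid[0] < mac_r else 2) + (0 if centroid[1] < mac_c else 1)
        quadrant_counts[quad] += 1
    nonempty = sum(1 for q in quadrant_counts if q > 0)
    return PrpDecision(
        is_prp=bool(n_marks >= config.min_marks and nonempty >= config.min_quadrants),
        n_marks=n_marks,
        quadrant_counts=tuple(quadrant_counts),
        violations=violations,
    )


def prp_confusion(
    decisions: Sequence[PrpDecision], truth: Sequence[bool]
) -> tuple[float, float, float]:
    """Image-level (sensitivity, specificity, accuracy) of PRP decisions."""
    if len(decisions) != len(truth):
        raise ClassificationError(f"{len(decisions)} decisions vs {len(truth)} truths")
    pred = np.array([d.is_prp for d in decisions], dtype=bool)
    t = np.array(truth, dtype=bool)
    tp = int(np.count_nonzero(pred & t))
    tn = int(np.count_nonzero(~pred & ~t))
    fp = int(np.count_nonzero(pred & ~t))
    fn = int(np.count_nonzero(~pred & t))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(t)
    return sens, spec, acc
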