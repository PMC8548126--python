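"""Clinically-derived denoising of laser-mark probability maps.

Photocoagulation burns are never placed on the optic disc or the macula, so
positive predictions there are false by construction.  Two masks implement
this: an elliptical zero-out at 1.8x the detected OD extents, and an 80-pixel
macula-centered square zero-out.  Both zero probabilities rather than
removing pixels, so downstream pixel-wise ROC analysis keeps the same pixel
universe; both are idempotent projections and commute.
"""

from __future__ import annotations

import numpy as np

from .anatomy import AnatomyFit, OdEllipse
from .fundus_io import ProbabilityMap

MACULA_SQUARE_SIDE = 80


def mask_od(pmap: ProbabilityMap, ellipse: OdEllipse) -> ProbabilityMap:
    """Zero all probabilities inside the OD exclusion ellipse."""
    values = pmap.values.copy()
    a, b = ellipse.semi_axis_x, ellipse.semi_axis_y
    if a > 0 and b > 0:
        rr, cc = np.mgrid[0 : values.shape[0], 0 : values.shape[1]]
        inside = ((cc - ellipse.center_col) / a) ** 2 + (
            (rr - ellipse.center_row) / b
        ) ** 2 <= 1.0
        values[inside] = 0.0
    return ProbabilityMap(values, id=pmap.id)


def mask_macula(
    pmap: ProbabilityMap,
    macula_center: tuple[float, float],
    side: int = MACULA_SQUARE_SIDE,
) -> ProbabilityMap:
    """Zero an axis-aligned macula-centered square, clipped to image bounds.

    For an even side the square spans ``[center - side//2, center + side//2 - 1]``
    in each axis.
    """
    values = pmap.values.copy()
    half = side // 2
    cr = int(round(macula_center[0]))
    cc = int(round(macula_center[1]))
    r0, r1 = max(0, cr - half), min(values.shape[0], cr - half + side)
    c0, c1 = max(0, cc - half), min(values.shape[1], cc - half + side)
    if r1 > r0 and c1 > c0:
        values[r0:r1, c0:c1] = 0.0
    return ProbabilityMap(values, id=pmap.id)


def postprocess_map(
    pmap: ProbabilityMap,
    anatomy: AnatomyFit,
    od_enabled: bool = True,
    macula_enabled: bool = True,
    macula_side: int = MACULA_SQUARE_SIDE,
) -> ProbabilityMap:
    """Apply the OD then the macula mask (both optional; order irrelevant)."""
    out = pmap
    if od_enabled:
        out = mask_od(out, anatomy.od_ellipse)
    if macula_enabled:
        out = mask_macula(out, anatomy.macula_center, side=macula_side)
    return out
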