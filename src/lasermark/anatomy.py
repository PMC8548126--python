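"""Optic-disc and macula localization for the anatomy-aware postprocessing.

The optic disc (OD) is segmented by a second network with the same
architecture and training process as the laser-mark network, trained against
OD masks; its binary prediction (threshold 0.5) is reduced to the largest
connected component, and the exclusion ellipse is 1.8x the component's
bounding-box extents.  The macula is localized by a simple photometric
surrogate: the minimum of the Gaussian-smoothed mean-channel intensity
inside a horizontal search band on the temporal side of the disc, 2-3
OD-widths from the disc center.  A micron-per-pixel scale is derived from
the OD extent under the standard clinical assumption of a 1800-micron disc
diameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label as cc_label

from .fundus_io import FundusSample, ProbabilityMap

OD_SCALE_FACTOR = 1.8
OD_DIAMETER_MICRONS = 1800.0
BINARIZE_THRESHOLD = 0.5


class LocalizationError(RuntimeError):
    pass


@dataclass
class OdEllipse:
    center_row: float
    center_col: float
    semi_axis_x: float  # columns
    semi_axis_y: float  # rows


@dataclass
class AnatomyFit:
    od_ellipse: OdEllipse
    od_extent: tuple[float, float]  # (max_x_len cols, max_y_len rows)
    macula_center: tuple[float, float]
    microns_per_pixel: float
    macula_low_confidence: bool = False

    def to_json(self, path: str | Path) -> None:
        d = {
            "od_center": [self.od_ellipse.center_row, self.od_ellipse.center_col],
            "od_semi_axes": [self.od_ellipse.semi_axis_x, self.od_ellipse.semi_axis_y],
            "od_extent": list(self.od_extent),
            "macula_center": list(self.macula_center),
            "microns_per_pixel": self.microns_per_pixel,
            "macula_low_confidence": self.macula_low_confidence,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnatomyFit":
        d = json.loads(Path(path).read_text())
        return cls(
            od_ellipse=OdEllipse(
                center_row=d["od_center"][0],
                center_col=d["od_center"][1],
                semi_axis_x=d["od_semi_axes"][0],
                semi_axis_y=d["od_semi_axes"][1],
            ),
            od_extent=tuple(d["od_extent"]),
            macula_center=tuple(d["macula_center"]),
            microns_per_pixel=d["microns_per_pixel"],
            macula_low_confidence=d.get("macula_low_confidence", False),
        )


@dataclass
class BinaryRegion:
    """A single 8-connected component of a binarized prediction map."""

    mask: np.ndarray
    component_id: int


def segment_od(sample: FundusSample, od_checkpoint, stats, **predict_kwargs) -> ProbabilityMap:
    """Optic-disc probability map via the standard preprocess-patch-predict chain.

    ``od_checkpoint`` must have been trained against OD masks;
    ``stats`` are the normalization statistics frozen with that checkpoint.
    """
    from .pipeline import predict_map  # local import: pipeline depends on this module

    return predict_map(sample, od_checkpoint, stats, **predict_kwargs)


def largest_component(pmap: ProbabilityMap, threshold: float = BINARIZE_THRESHOLD) -> BinaryRegion:
    """Largest 8-connected component of ``pmap >= threshold``.

    Ties in pixel count are broken by the smallest label in scan order.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    binary = pmap.values >= threshold
    if not binary.any():
        raise LocalizationError(
            f"map {pmap.id!r}: no pixel reaches threshold {threshold}"
        )
    labels, n = cc_label(binary, connectivity=2, return_num=True)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    best = int(counts.argmax())  # argmax takes the smallest label on ties
    return BinaryRegion(mask=(labels == best).astype(np.uint8), component_id=best)


def fit_od_ellipse(region: BinaryRegion, scale_factor: float = OD_SCALE_FACTOR):
    """OD exclusion ellipse: centroid-centered, semi-axes = scale * bbox extents / 2."""
    rows, cols = np.nonzero(region.mask)
    if len(rows) == 0:
        raise LocalizationError("empty region")
    max_y_len = float(rows.max() - rows.min() + 1)
    max_x_len = float(cols.max() - cols.min() + 1)
    ellipse = OdEllipse(
        center_row=float(rows.mean()),
        center_col=float(cols.mean()),
        semi_axis_x=scale_factor * max_x_len / 2.0,
        semi_axis_y=scale_factor * max_y_len / 2.0,
    )
    return ellipse, (max_x_len, max_y_len)


def locate_macula(
    sample_image: np.ndarray,
    od_ellipse: OdEllipse,
    od_extent: tuple[float, float],
    smoothing_sigma: float = 5.0,
) -> tuple[tuple[int, int], bool]:
    """Macula center as the darkest smoothed point in a temporal search band.

    The band is centered on the OD center row (half-height one OD y-extent)
    and spans 2-3 OD x-extents from the OD center on the temporal side (the
    side away from the nearer vertical image edge).  Returns the (row, col)
    of the minimum and a low-confidence flag set when the band is constant.
    """
    img = np.asarray(sample_image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    n_rows, n_cols = img.shape
    od_r, od_c = od_ellipse.center_row, od_ellipse.center_col
    width_x, width_y = od_extent

    temporal = 1 if od_c < n_cols / 2 else -1  # away from the nearer vertical edge
    c_near = od_c + temporal * 2.0 * width_x
    c_far = od_c + temporal * 3.0 * width_x
    c_lo = int(np.floor(min(c_near, c_far)))
    c_hi = int(np.ceil(max(c_near, c_far)))
    r_lo = int(np.floor(od_r - width_y))
    r_hi = int(np.ceil(od_r + width_y))
    r_lo, r_hi = max(0, r_lo), min(n_rows - 1, r_hi)
    c_lo, c_hi = max(0, c_lo), min(n_cols - 1, c_hi)
    if r_lo > r_hi or c_lo > c_hi:
        raise LocalizationError("macula search window is empty (OD at image edge?)")

    smoothed = gaussian_filter(img, sigma=smoothing_sigma)
    window = smoothed[r_lo : r_hi + 1, c_lo : c_hi + 1]
    flat = int(window.argmin())  # ties: first position in scan order
    dr, dc = np.unravel_index(flat, window.shape)
    low_confidence = bool(np.ptp(window) < 1e-9)
    return (r_lo + int(dr), c_lo + int(dc)), low_confidence


def estimate_scale(
    od_extent: tuple[float, float], od_diameter_microns: float = OD_DIAMETER_MICRONS
) -> float:
    """Microns per pixel assuming the OD extent spans ``od_diameter_microns``."""
    mean_ext = (od_extent[0] + od_extent[1]) / 2.0
    if mean_ext <= 0:
        raise LocalizationError("OD extent is zero; cannot estimate scale")
    return od_diameter_microns / mean_ext


def fit_anatomy(
    sample: FundusSample,
    od_map: ProbabilityMap,
    threshold: float = BINARIZE_THRESHOLD,
    scale_factor: float = OD_SCALE_FACTOR,
    od_diameter_microns: float = OD_DIAMETER_MICRONS,
    macula_center: Optional[tuple[float, float]] = None,
) -> AnatomyFit:
    """Full anatomy fit from an OD probability map (and optionally a known macula)."""
    region = largest_component(od_map, threshold)
    ellipse, extent = fit_od_ellipse(region, scale_factor)
    low_conf = False
    if macula_center is None:
        macula_center, low_conf = locate_macula(sample.image, ellipse, extent)
    return AnatomyFit(
        od_ellipse=ellipse,
        od_extent=extent,
        macula_center=tuple(map(float, macula_center)),
        microns_per_pixel=estimate_scale(extent, od_diameter_microns),
        macula_low_confidence=low_conf,
    )
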