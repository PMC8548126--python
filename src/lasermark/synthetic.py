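"""Synthetic fundus photographs with per-pixel ground truth.

The generator emulates the features of clinical color fundus photographs that
the segmentation pipeline actually exercises: a circular field of view on a
strictly black background, a radial hue gradient (whitish / yellowish /
reddish camera tones), dark curvilinear vessel tracks radiating from a bright
elliptical optic disc, a dark macular region roughly 2.5 optic-disc diameters
temporal to the disc, and scattered round laser-burn scars rendered as bright
discs with a darker pigmented rim.  Every image carries an exact lesion mask,
an optic-disc mask, a vessel mask and the macula center, so every downstream
stage can be tested without clinical data.

Laser-mark placement respects the clinical constraints the postprocessing
relies on: no mark is placed inside the optic-disc exclusion ellipse (1.8x
the disc extents, plus a safety margin) or inside the macular exclusion zone.
A ``prp`` pattern scatters marks in all four macula-centered quadrants, a
``partial`` pattern confines them to a single quadrant, and ``none`` places
no marks at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage.draw import bezier_curve, disk

from .fundus_io import Manifest, save_sample, write_manifest, FundusSample

HUE_PROFILES = {
    "whitish": (205.0, 190.0, 175.0),
    "yellowish": (195.0, 160.0, 85.0),
    "reddish": (175.0, 85.0, 55.0),
}

PATTERNS = ("prp", "partial", "none", "mixed")

# Prevalence of laser-mark patterns in the kind of referral population the
# pipeline targets (PRP / partial laser / no laser).
MIXED_PATTERN_PROBS = {"prp": 0.513, "partial": 0.422, "none": 0.065}


class GenerationError(RuntimeError):
    """Raised when a scene cannot be realized (e.g. mark placement fails)."""


@dataclass
class SynthConfig:
    """Conditions under which synthetic fundus images are drawn.

    ``seed`` fixes the full output byte-for-byte; each image derives its own
    RNG from a hierarchical seed sequence, so changing ``n_images`` never
    reshuffles earlier images.
    """

    seed: int = 0
    n_images: int = 10
    size_range: tuple[int, int] = (560, 720)
    hue_profile: str = "random"  # one of HUE_PROFILES or "random"
    n_laser_marks_range: tuple[int, int] = (40, 70)
    laser_radius_range: tuple[int, int] = (5, 9)
    pattern: str = "prp"
    vessel_count: int = 6
    noise_sd: float = 2.0
    train_fraction: float = 0.7
    mark_contrast: float = 1.0  # separability knob for fast tests
    camera_variation: float = 1.0  # scales between-image hue/brightness jitter
    max_place_attempts: int = 1000

    def __post_init__(self) -> None:
        for name in ("size_range", "n_laser_marks_range", "laser_radius_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is degenerate: {lo} > {hi}")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        if self.hue_profile != "random" and self.hue_profile not in HUE_PROFILES:
            raise ValueError(f"unknown hue_profile {self.hue_profile!r}")


@dataclass
class Scene:
    """One rendered synthetic fundus with all its ground truth."""

    image: np.ndarray
    lesion_mask: np.ndarray
    od_mask: np.ndarray
    vessel_mask: np.ndarray
    macula_center: tuple[float, float]
    od_center: tuple[float, float]
    od_semi_axes: tuple[float, float]  # (semi_y rows, semi_x cols)
    pattern: str


def _fov(size: int, rng: np.random.Generator):
    """Field of view mask, center, radius, and a feathered edge weight.

    The brightness rolls off smoothly over a few pixels inside the aperture
    (cameras vignette, they do not cut) and is exactly zero outside it.
    """
    radius = size * rng.uniform(0.44, 0.47)
    center = size / 2.0
    rr, cc = np.mgrid[0:size, 0:size]
    dist = np.hypot(rr - center, cc - center)
    feather = max(2.0, 0.035 * size)
    weight = np.clip((radius - dist) / feather, 0.0, 1.0)
    return dist <= radius, (center, center), radius, weight


def _ellipse_mask(shape, center, semi_y, semi_x) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / semi_y) ** 2 + ((cc - center[1]) / semi_x) ** 2 <= 1.0


def _draw_vessels(size, od_center, fov_radius, fov_center, n, rng) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    r0, c0 = int(round(od_center[0])), int(round(od_center[1]))
    for _ in range(n):
        ang = rng.uniform(0, 2 * math.pi)
        reach = fov_radius * rng.uniform(0.75, 0.98)
        r2 = int(round(fov_center[0] + reach * math.sin(ang)))
        c2 = int(round(fov_center[1] + reach * math.cos(ang)))
        # a bowed control point gives the arcade-like curvature
        mid_r = (r0 + r2) / 2 + rng.uniform(-0.2, 0.2) * size
        mid_c = (c0 + c2) / 2 + rng.uniform(-0.2, 0.2) * size
        rr, cc = bezier_curve(r0, c0, int(mid_r), int(mid_c), r2, c2, weight=1.0,
                              shape=(size, size))
        mask[rr, cc] = True
    thickness = max(1, size // 350)
    return binary_dilation(mask, iterations=thickness)


def _place_marks(rng, cfg: SynthConfig, pattern: str, fov_center, fov_radius,
                 od_center, od_semi, macula, size) -> list[tuple[int, int, int]]:
    """Rejection-sample mark centers (row, col, radius) under the clinical constraints."""
    if pattern == "none":
        return []
    n = int(rng.integers(cfg.n_laser_marks_range[0], cfg.n_laser_marks_range[1] + 1))
    if pattern == "partial":
        n = max(3, n // 4)  # incomplete treatment: far fewer scars, one sector
    # exclusion geometry: the postprocessing ellipse is 1.8x the OD extents;
    # keep whole marks out of it, and out of a macular zone wide enough that
    # the 3000-micron PRP rule cannot clip legitimate marks.
    od_excl_y, od_excl_x = 1.8 * od_semi[0], 1.8 * od_semi[1]
    margin = 0.035 * size
    mac_excl = 0.20 * size

    if pattern == "partial":
        # confine to a quadrant on the side away from the OD, where the
        # exclusion zones leave room for a cluster of marks
        col_side = 0 if od_center[1] > macula[1] else 1
        sector = int(rng.integers(0, 2)) * 2 + col_side
    placed: list[tuple[int, int, int]] = []
    for k in range(n):
        r_mark = int(rng.integers(cfg.laser_radius_range[0], cfg.laser_radius_range[1] + 1))
        for attempt in range(cfg.max_place_attempts):
            rr = rng.uniform(fov_center[0] - fov_radius, fov_center[0] + fov_radius)
            cc = rng.uniform(fov_center[1] - fov_radius, fov_center[1] + fov_radius)
            if pattern == "prp" and k < 4:
                # guarantee one mark per macula-centered quadrant
                want = k
            elif pattern == "partial":
                want = sector
            else:
                want = None
            if want is not None:
                # fold the candidate into the wanted macula-centered quadrant
                sign_r = -1.0 if want in (0, 1) else 1.0
                sign_c = -1.0 if want in (0, 2) else 1.0
                rr = macula[0] + sign_r * abs(rr - macula[0])
                cc = macula[1] + sign_c * abs(cc - macula[1])
            feather = max(2.0, 0.035 * size)
            if (math.hypot(rr - fov_center[0], cc - fov_center[1])
                    > fov_radius - r_mark - 2 - feather):
                continue
            dq_r, dq_c = rr - macula[0], cc - macula[1]
            # outside the inflated OD exclusion ellipse
            ey = od_excl_y + r_mark + margin
            ex = od_excl_x + r_mark + margin
            if ((rr - od_center[0]) / ey) ** 2 + ((cc - od_center[1]) / ex) ** 2 <= 1.0:
                continue
            # outside the macular exclusion zone
            if math.hypot(dq_r, dq_c) <= mac_excl + r_mark:
                continue
            # marks must stay disjoint (each scar is one connected component)
            if any(math.hypot(rr - pr, cc - pc) < r_mark + pr_r + 3
                   for pr, pc, pr_r in placed):
                continue
            placed.append((int(round(rr)), int(round(cc)), r_mark))
            break
        else:
            raise GenerationError(
                f"could not place laser mark {k + 1}/{n} after "
                f"{cfg.max_place_attempts} attempts (pattern={pattern}, size={size})"
            )
    return placed


def render_scene(cfg: SynthConfig, rng: np.random.Generator) -> Scene:
    """Render one synthetic fundus scene under ``cfg`` using ``rng``."""
    if cfg.pattern == "mixed":
        raise ValueError("render_scene needs a concrete pattern; 'mixed' is resolved per image by generate_dataset")
    size = int(rng.integers(cfg.size_range[0], cfg.size_range[1] + 1))
    fov_mask, fov_center, fov_radius, fov_weight = _fov(size, rng)

    hue = cfg.hue_profile
    if hue == "random":
        hue = list(HUE_PROFILES)[int(rng.integers(0, len(HUE_PROFILES)))]
    base = np.array(HUE_PROFILES[hue]) + rng.uniform(-10, 10, size=3) * cfg.camera_variation

    rr, cc = np.mgrid[0:size, 0:size]
    radial = 1.0 - 0.45 * np.clip(
        np.hypot(rr - fov_center[0], cc - fov_center[1]) / fov_radius, 0, 1
    ) ** 2
    img = base[None, None, :] * radial[:, :, None]

    # optic disc: bright vertical ellipse left or right of center
    side = -1 if rng.random() < 0.5 else 1
    od_center = (
        fov_center[0] + rng.uniform(-0.04, 0.04) * size,
        fov_center[1] + side * rng.uniform(0.26, 0.32) * size,
    )
    od_sx = 0.055 * size * rng.uniform(0.9, 1.1)
    od_sy = od_sx * rng.uniform(1.05, 1.2)
    od_mask = _ellipse_mask((size, size), od_center, od_sy, od_sx)
    od_soft = gaussian_filter(od_mask.astype(float), sigma=size / 250)
    od_color = np.array([235.0, 218.0, 185.0])
    img = img * (1 - od_soft[:, :, None]) + od_color[None, None, :] * od_soft[:, :, None]

    # macula: dark smooth blob ~2.5 OD diameters temporal to the disc
    macula = (
        od_center[0] + rng.uniform(-0.01, 0.01) * size,
        od_center[1] - side * 2.5 * (2 * od_sx),
    )
    sigma_mac = 0.040 * size
    mac_bump = np.exp(
        -((rr - macula[0]) ** 2 + (cc - macula[1]) ** 2) / (2 * sigma_mac**2)
    )
    img *= 1.0 - 0.35 * mac_bump[:, :, None]

    vessel_mask = _draw_vessels(size, od_center, fov_radius, fov_center,
                                cfg.vessel_count, rng)
    img[vessel_mask] *= 0.45

    marks = _place_marks(rng, cfg, cfg.pattern, fov_center, fov_radius,
                         od_center, (od_sy, od_sx), macula, size)
    lesion = np.zeros((size, size), dtype=np.uint8)
    contrast = cfg.mark_contrast
    mark_color = np.array([245.0, 235.0, 215.0])
    for mr, mc, mrad in marks:
        rr_d, cc_d = disk((mr, mc), mrad, shape=(size, size))
        alpha = min(1.0, 0.85 * contrast)
        img[rr_d, cc_d] = img[rr_d, cc_d] * (1 - alpha) + mark_color[None, :] * alpha
        lesion[rr_d, cc_d] = 1
        rim_r, rim_c = disk((mr, mc), mrad + 2, shape=(size, size))
        rim = np.zeros((size, size), dtype=bool)
        rim[rim_r, rim_c] = True
        rim[rr_d, cc_d] = False
        img[rim] *= max(0.0, 1.0 - 0.5 * contrast)

    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img *= fov_weight[:, :, None]  # smooth vignette, exactly 0 outside
    img = np.clip(img, 0, 255)
    img[~fov_mask] = 0.0  # exterior strictly black in all channels
    lesion[~fov_mask] = 0
    od_mask = od_mask & fov_mask
    vessel_mask = vessel_mask & fov_mask
    return Scene(
        image=img.astype(np.uint8),
        lesion_mask=lesion,
        od_mask=od_mask.astype(np.uint8),
        vessel_mask=vessel_mask.astype(np.uint8),
        macula_center=macula,
        od_center=od_center,
        od_semi_axes=(od_sy, od_sx),
        pattern=cfg.pattern,
    )


def _image_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _generate(cfg: SynthConfig, out_dir: Path, label_source: str) -> Manifest:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_train = int(math.ceil(cfg.train_fraction * cfg.n_images))
    rows = []
    for i in range(cfg.n_images):
        rng = _image_rng(cfg.seed, i)
        img_cfg = cfg
        if cfg.pattern == "mixed":
            u = rng.random()
            acc, chosen = 0.0, "none"
            for pat, p in MIXED_PATTERN_PROBS.items():
                acc += p
                if u < acc:
                    chosen = pat
                    break
            img_cfg = replace(cfg, pattern=chosen)
        scene = render_scene(img_cfg, rng)
        label = scene.vessel_mask if label_source == "vessel" else scene.lesion_mask
        sample = FundusSample(
            id=f"synth_{i:04d}",
            image=scene.image,
            lesion_mask=label,
            od_mask=scene.od_mask,
            macula_center=scene.macula_center,
            split="train" if i < n_train else "test",
        )
        paths = save_sample(sample, out_dir)
        rows.append(
            {
                "id": sample.id,
                "image": str(paths["image"]),
                "lesion_mask": str(paths["lesion_mask"]),
                "od_mask": str(paths["od_mask"]),
                "split": sample.split,
                "macula_row": scene.macula_center[0],
                "macula_col": scene.macula_center[1],
                "pattern": img_cfg.pattern,
            }
        )
    return write_manifest(rows, out_dir / "manifest.csv", root=out_dir)


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> Manifest:
    """Write ``cfg.n_images`` synthetic fundus samples whose labels are laser marks."""
    return _generate(cfg, Path(out_dir), label_source="lesion")


def generate_vessel_pretraining_set(cfg: SynthConfig, out_dir: str | Path) -> Manifest:
    """Write a pretraining set whose ground truth is the vessel tracks.

    Stands in for a public vessel-segmentation dataset when staging the
    transfer-learning chain: same scenes as :func:`generate_dataset`, but the
    ``lesion_mask`` column points at the vessel mask.
    """
    return _generate(cfg, Path(out_dir), label_source="vessel")
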