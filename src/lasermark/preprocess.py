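"""Photometric normalization of fundus photographs.

The chain is applied per channel, in this order:

1. resize to a square canonical side (bilinear for images, nearest for masks);
2. Z-score standardization against per-pixel-position training-set statistics,
   ``z = (x - mu) / sigma`` with ``sigma`` the population standard deviation;
3. per-image min-max rescale of each channel back to [0, 255];
4. CLAHE followed by gamma correction with exponent 1/1.2;
5. division by 255 into [0, 1].

The per-pixel-position statistics are fitted on the training split only and
frozen; test images are standardized with the training statistics.  Pixels
that are zero in all channels of the resized input (the field-of-view
exterior) are re-zeroed at the end of the chain, because the min-max step
would otherwise lift the uninformative black surround to a nonzero gray and
the downstream black-patch exclusion could never trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from pathlib import Path

import h5py
import numpy as np
from skimage.exposure import equalize_adapthist
from skimage.transform import resize as sk_resize

from .fundus_io import FundusSample, SampleError

CANONICAL_SIDE = 512
DEFAULT_CLIP_LIMIT = 2.0  # bins-multiple convention: 1.0 = uniform histogram height
DEFAULT_TILE_GRID = 8
GAMMA_EXPONENT = 1.0 / 1.2
_CLAHE_NBINS = 256


@dataclass
class NormStats:
    """Per-pixel-position, per-channel mean and population SD of the training set."""

    mu: np.ndarray  # (side, side, 3)
    sigma: np.ndarray  # (side, side, 3)
    n_images: int
    side: int

    def __post_init__(self) -> None:
        expected = (self.side, self.side, 3)
        if self.mu.shape != expected or self.sigma.shape != expected:
            raise ValueError(
                f"stats shape mismatch: mu {self.mu.shape}, sigma {self.sigma.shape}, "
                f"expected {expected}"
            )
        if (self.sigma < 0).any():
            raise ValueError("sigma must be non-negative")

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("mu", data=self.mu)
            f.create_dataset("sigma", data=self.sigma)
            f.attrs["n_images"] = self.n_images
            f.attrs["side"] = self.side

    @classmethod
    def load(cls, path: str | Path) -> "NormStats":
        with h5py.File(path, "r") as f:
            return cls(
                mu=f["mu"][...],
                sigma=f["sigma"][...],
                n_images=int(f.attrs["n_images"]),
                side=int(f.attrs["side"]),
            )


@dataclass
class PreprocessedImage:
    """Canonical-size image after the full normalization chain, values in [0, 1]."""

    values: np.ndarray  # (side, side, 3) float
    id: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3 or v.shape[2] != 3:
            raise ValueError(f"expected side x side x 3, got {v.shape}")
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError(f"values outside [0, 1]: [{v.min():.4g}, {v.max():.4g}]")


def resize_to_canonical(sample: FundusSample, side: int = CANONICAL_SIDE) -> FundusSample:
    """Resize a sample to ``side x side``: bilinear image, nearest-neighbor masks."""
    if side <= 0:
        raise ValueError("side must be positive")
    if sample.shape == (side, side):
        return sample

    def _img(a):
        out = sk_resize(a.astype(float), (side, side), order=1,
                        anti_aliasing=False, preserve_range=True)
        return np.clip(out, 0, 255).astype(np.uint8)

    def _mask(a):
        if a is None:
            return None
        out = sk_resize(a, (side, side), order=0, anti_aliasing=False,
                        preserve_range=True)
        return (out > 0.5).astype(np.uint8)

    macula = sample.macula_center
    if macula is not None:
        sr = side / sample.shape[0]
        sc = side / sample.shape[1]
        macula = (macula[0] * sr, macula[1] * sc)
    return FundusSample(
        id=sample.id,
        image=_img(sample.image),
        lesion_mask=_mask(sample.lesion_mask),
        od_mask=_mask(sample.od_mask),
        macula_center=macula,
        split=sample.split,
    )


def fit_norm_stats(train_images: list[np.ndarray]) -> NormStats:
    """Fit per-pixel-position, per-channel mean and population SD over the training images."""
    if len(train_images) < 2:
        raise ValueError(f"need at least 2 training images, got {len(train_images)}")
    side = train_images[0].shape[0]
    for img in train_images:
        if img.shape != (side, side, 3):
            raise ValueError(f"all images must be ({side}, {side}, 3); got {img.shape}")
    stack = np.stack([np.asarray(img, dtype=np.float64) for img in train_images])
    mu = stack.mean(axis=0)
    sigma = stack.std(axis=0)  # population SD (ddof=0)
    return NormStats(mu=mu, sigma=sigma, n_images=len(train_images), side=side)


def standardize(image: np.ndarray, stats: NormStats) -> np.ndarray:
    """Z-score an image against frozen training statistics; z = 0 where sigma = 0."""
    x = np.asarray(image, dtype=np.float64)
    if x.shape != stats.mu.shape:
        raise ValueError(f"image shape {x.shape} does not match stats {stats.mu.shape}")
    z = np.zeros_like(x)
    ok = stats.sigma > 0
    z[ok] = (x[ok] - stats.mu[ok]) / stats.sigma[ok]
    return z


def minmax_rescale(z: np.ndarray) -> np.ndarray:
    """Per-channel, per-image linear map of ``z`` onto [0, 255].

    A constant channel (max == min) maps to all zeros.
    """
    z = np.asarray(z, dtype=np.float64)
    out = np.zeros_like(z)
    for k in range(z.shape[-1]):
        ch = z[..., k]
        lo, hi = ch.min(), ch.max()
        if hi > lo:
            out[..., k] = (ch - lo) / (hi - lo) * 255.0
    return out


def clahe_gamma(
    v: np.ndarray,
    clip_limit: float = DEFAULT_CLIP_LIMIT,
    tile_grid: int = DEFAULT_TILE_GRID,
    apply_clahe: bool = True,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization then gamma correction.

    CLAHE runs per channel on a ``tile_grid x tile_grid`` tiling; ``clip_limit``
    caps each histogram bin at ``clip_limit`` times the uniform bin height.
    The gamma step computes ``255 * (v / 255) ** (1/1.2)`` (a brightening
    exponent of about 0.833) and the result is clamped to [0, 255].
    """
    v = np.asarray(v, dtype=np.float64)
    out = np.empty_like(v)
    side = v.shape[0]
    kernel = max(1, side // tile_grid)
    for k in range(v.shape[-1]):
        ch = v[..., k]
        if apply_clahe:
            ch = equalize_adapthist(
                np.clip(ch / 255.0, 0, 1),
                kernel_size=kernel,
                clip_limit=clip_limit / _CLAHE_NBINS,
                nbins=_CLAHE_NBINS,
            ) * 255.0
        out[..., k] = 255.0 * np.clip(ch / 255.0, 0, 1) ** GAMMA_EXPONENT
    return np.clip(out, 0, 255)


def preprocess_image(
    sample: FundusSample,
    stats: NormStats,
    clip_limit: float = DEFAULT_CLIP_LIMIT,
    tile_grid: int = DEFAULT_TILE_GRID,
    apply_clahe: bool = True,
) -> PreprocessedImage:
    """Run the full per-channel chain; output values in [0, 1]."""
    canonical = resize_to_canonical(sample, stats.side)
    x = canonical.image.astype(np.float64)
    z = standardize(x, stats)
    v = minmax_rescale(z)
    v = clahe_gamma(v, clip_limit=clip_limit, tile_grid=tile_grid,
                    apply_clahe=apply_clahe)
    out = v / 255.0
    # the field-of-view exterior carries no signal; keep it at exactly zero
    exterior = (x == 0).all(axis=-1)
    out[exterior] = 0.0
    return PreprocessedImage(values=out, id=sample.id)
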