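"""Patch augmentation for training and sliding-window extraction/reassembly for inference.

Training uses randomly centered square windows drawn uniformly over positions
where the full window fits inside the image; windows that are entirely zero
in all channels (peripheral black area, no information) are rejected and
redrawn.  Inference slides a window with a fixed stride; windows overhanging
the right/lower margin are zero-padded when fed to the network, and the
padded area is excluded from the overlap-averaged reassembly so border
probabilities are not diluted by padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_WINDOW = 48
DEFAULT_STRIDE = 5
DEFAULT_N_PER_IMAGE = 10_000
REJECTION_CAP_FACTOR = 100


class ExtractionError(RuntimeError):
    """Raised when random patch extraction cannot find enough informative windows."""


@dataclass
class PatchSet:
    """Aligned image/label windows with their center coordinates."""

    images: np.ndarray  # (n, window, window, 3) float32 in [0, 1]
    labels: np.ndarray  # (n, window, window) uint8
    centers: np.ndarray  # (n, 2) int (row, col)
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.images)

    @staticmethod
    def concatenate(sets: list["PatchSet"]) -> "PatchSet":
        return PatchSet(
            images=np.concatenate([s.images for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            centers=np.concatenate([s.centers for s in sets]),
            source_id="+".join(s.source_id for s in sets),
        )


@dataclass
class SlidePlan:
    """Ordered top-left window origins covering an extent with a fixed stride."""

    origins: list[tuple[int, int]]
    stride: int
    window: int
    padded_extent: tuple[int, int]


def extract_random_patches(
    image: np.ndarray,
    label: np.ndarray,
    n: int,
    window: int = DEFAULT_WINDOW,
    rng_seed: int = 0,
) -> PatchSet:
    """Draw ``n`` randomly centered windows, excluding completely black patches.

    Centers are uniform over positions where the window lies fully inside the
    image.  A window of even side ``w`` centered at ``c`` spans rows
    ``[c - w//2, c + w//2)``.  Candidates whose image window is zero in every
    channel are rejected and redrawn, up to ``100 * n`` attempts in total.
    """
    image = np.asarray(image)
    label = np.asarray(label)
    side_r, side_c = image.shape[:2]
    if window > min(side_r, side_c):
        raise ValueError(f"window {window} exceeds image extent {image.shape[:2]}")
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return PatchSet(
            images=np.empty((0, window, window, 3), np.float32),
            labels=np.empty((0, window, window), np.uint8),
            centers=np.empty((0, 2), int),
        )

    half = window // 2
    lo_r, hi_r = half, side_r - (window - half)  # inclusive center range
    lo_c, hi_c = half, side_c - (window - half)
    rng = np.random.default_rng(rng_seed)

    # summed-area table over the channel sum: a window is all-zero in every
    # channel iff its integral-image sum is zero (values are non-negative)
    channel_sum = image.reshape(side_r, side_c, -1).sum(axis=-1)
    sat = np.zeros((side_r + 1, side_c + 1))
    sat[1:, 1:] = channel_sum.cumsum(axis=0).cumsum(axis=1)

    cap = REJECTION_CAP_FACTOR * n
    attempts = 0
    rows_acc: list[np.ndarray] = []
    cols_acc: list[np.ndarray] = []
    n_accepted = 0
    while n_accepted < n:
        remaining = n - n_accepted
        batch = min(max(remaining * 2, 64), cap - attempts)
        if batch <= 0:
            raise ExtractionError(
                f"rejection cap of {cap} attempts exceeded with "
                f"{n_accepted}/{n} patches accepted (image nearly all black?)"
            )
        attempts += batch
        cr = rng.integers(lo_r, hi_r + 1, size=batch)
        cc = rng.integers(lo_c, hi_c + 1, size=batch)
        r0, c0 = cr - half, cc - half
        sums = (
            sat[r0 + window, c0 + window]
            - sat[r0, c0 + window]
            - sat[r0 + window, c0]
            + sat[r0, c0]
        )
        ok = sums > 0
        cr, cc = cr[ok][:remaining], cc[ok][:remaining]
        rows_acc.append(cr)
        cols_acc.append(cc)
        n_accepted += len(cr)

    centers_r = np.concatenate(rows_acc)
    centers_c = np.concatenate(cols_acc)
    r0 = centers_r - half
    c0 = centers_c - half
    img_view = np.lib.stride_tricks.sliding_window_view(image, (window, window),
                                                        axis=(0, 1))
    lbl_view = np.lib.stride_tricks.sliding_window_view(label, (window, window),
                                                        axis=(0, 1))
    # img_view: (H-w+1, W-w+1, C, w, w) -> gather and move channels last
    patches = np.moveaxis(img_view[r0, c0], 1, -1).astype(np.float32)
    label_patches = lbl_view[r0, c0].astype(np.uint8)
    return PatchSet(
        images=patches,
        labels=label_patches,
        centers=np.stack([centers_r, centers_c], axis=1).astype(int),
    )


def plan_sliding(
    extent: tuple[int, int], window: int = DEFAULT_WINDOW, stride: int = DEFAULT_STRIDE
) -> SlidePlan:
    """Plan window origins at ``0, s, 2s, ...`` up to the last origin < extent.

    Every source pixel is covered by at least one window (requires
    ``stride <= window``); trailing windows overhang and are zero-padded at
    extraction time.
    """
    if stride < 1 or window < 1:
        raise ValueError("stride and window must be >= 1")
    if stride > window:
        raise ValueError(f"stride {stride} > window {window} would leave uncovered pixels")
    rows, cols = extent
    r_origins = list(range(0, rows, stride))
    c_origins = list(range(0, cols, stride))
    origins = [(r, c) for r in r_origins for c in c_origins]
    padded = (r_origins[-1] + window, c_origins[-1] + window)
    return SlidePlan(origins=origins, stride=stride, window=window, padded_extent=padded)


def extract_plan_windows(image: np.ndarray, plan: SlidePlan) -> np.ndarray:
    """Materialize the plan's windows from an image, zero-padding overhangs."""
    rows, cols = image.shape[:2]
    pad_r = plan.padded_extent[0] - rows
    pad_c = plan.padded_extent[1] - cols
    pad_width = [(0, max(0, pad_r)), (0, max(0, pad_c))] + [(0, 0)] * (image.ndim - 2)
    padded = np.pad(image, pad_width)
    w = plan.window
    out = np.empty((len(plan.origins), w, w) + image.shape[2:], dtype=image.dtype)
    for i, (r, c) in enumerate(plan.origins):
        out[i] = padded[r : r + w, c : c + w]
    return out


def reassemble(
    patch_predictions: list[tuple[tuple[int, int], np.ndarray]],
    plan: SlidePlan,
    extent: tuple[int, int],
) -> np.ndarray:
    """Average overlapping window predictions into a full-size map.

    Each pixel's value is the sum of the predictions covering it divided by
    the number of windows covering it.  Padded (overhanging) window regions
    are discarded, not averaged.
    """
    provided = {origin: win for origin, win in patch_predictions}
    missing = [o for o in plan.origins if o not in provided]
    if missing:
        raise ValueError(f"missing predictions for origins {missing[:5]}...")
    rows, cols = extent
    acc = np.zeros((rows, cols), dtype=np.float64)
    cnt = np.zeros((rows, cols), dtype=np.int64)
    w = plan.window
    for origin in plan.origins:
        r, c = origin
        win = np.asarray(provided[origin], dtype=np.float64)
        vr = min(w, rows - r)
        vc = min(w, cols - c)
        acc[r : r + vr, c : c + vc] += win[:vr, :vc]
        cnt[r : r + vr, c : c + vc] += 1
    if (cnt == 0).any():
        raise ValueError("sliding plan does not cover the full extent")
    return acc / cnt
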