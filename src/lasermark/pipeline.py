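"""End-to-end orchestration: manifest -> stats -> patches -> network -> maps.

Thin glue over the library modules so the CLI, the examples, and the tests
all run the identical chain.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import anatomy as anat
from .fundus_io import FundusSample, Manifest, ProbabilityMap, load_sample
from .lwunet import Checkpoint, NetworkSpec, TrainConfig, predict_patches, train
from .patchwork import (
    PatchSet,
    extract_plan_windows,
    extract_random_patches,
    plan_sliding,
    reassemble,
)
from .postprocess import postprocess_map
from .preprocess import NormStats, fit_norm_stats, preprocess_image, resize_to_canonical


def load_split_samples(manifest: Manifest, split: str) -> list[FundusSample]:
    return [load_sample(rec) for rec in manifest.subset(split).records]


def fit_stats(samples: Sequence[FundusSample], side: int) -> NormStats:
    """Fit per-pixel normalization statistics on canonical-size training images."""
    canonical = [resize_to_canonical(s, side).image for s in samples]
    return fit_norm_stats(canonical)


def build_patch_pool(
    samples: Sequence[FundusSample],
    stats: NormStats,
    n_per_image: int,
    window: int = 48,
    seed: int = 0,
    label_attr: str = "lesion_mask",
    **preprocess_kwargs,
) -> PatchSet:
    """Preprocess each training image and extract its random patch set."""
    sets = []
    for i, sample in enumerate(samples):
        pre = preprocess_image(sample, stats, **preprocess_kwargs)
        canonical = resize_to_canonical(sample, stats.side)
        label = getattr(canonical, label_attr)
        ps = extract_random_patches(
            pre.values, label, n=n_per_image, window=window,
            rng_seed=seed + i,
        )
        ps.source_id = sample.id
        sets.append(ps)
    return PatchSet.concatenate(sets)


def train_from_manifest(
    manifest: Manifest,
    stats: NormStats,
    train_config: TrainConfig,
    network_spec: Optional[NetworkSpec] = None,
    n_per_image: int = 500,
    window: int = 48,
    init: Optional[Checkpoint] = None,
    label_attr: str = "lesion_mask",
    norm_stats_ref: str = "",
    **preprocess_kwargs,
) -> Checkpoint:
    samples = load_split_samples(manifest, "train")
    pool = build_patch_pool(
        samples, stats, n_per_image=n_per_image, window=window,
        seed=train_config.seed, label_attr=label_attr, **preprocess_kwargs,
    )
    return train(pool, train_config, init=init, spec=network_spec,
                 norm_stats_ref=norm_stats_ref)


def predict_map(
    sample: FundusSample,
    checkpoint: Checkpoint,
    stats: NormStats,
    stride: int = 5,
    batch_size: int = 256,
    **preprocess_kwargs,
) -> ProbabilityMap:
    """Preprocess, slide, predict and overlap-average one image into a probability map."""
    pre = preprocess_image(sample, stats, **preprocess_kwargs)
    window = checkpoint.network_spec.window
    extent = pre.values.shape[:2]
    plan = plan_sliding(extent, window=window, stride=stride)
    windows = extract_plan_windows(pre.values.astype(np.float32), plan)
    probs = predict_patches(checkpoint, windows, batch_size=batch_size)
    values = reassemble(list(zip(plan.origins, probs)), plan, extent)
    # the all-black field-of-view exterior carries no signal and is excluded
    # from training (black-patch rule); pin its probability at zero
    values[(pre.values == 0.0).all(axis=-1)] = 0.0
    return ProbabilityMap(np.clip(values, 0.0, 1.0), id=sample.id)


def anatomy_from_truth(sample: FundusSample, side: int) -> anat.AnatomyFit:
    """Anatomy fit derived from ground-truth OD masks and annotated macula centers.

    Used when evaluating postprocessing in isolation from the OD network:
    the ground-truth OD mask plays the role of a perfect OD probability map.
    """
    canonical = resize_to_canonical(sample, side)
    if canonical.od_mask is None:
        raise anat.LocalizationError(f"sample {sample.id!r} has no OD mask")
    od_map = ProbabilityMap(canonical.od_mask.astype(float), id=sample.id)
    return anat.fit_anatomy(canonical, od_map, macula_center=canonical.macula_center)


def anatomy_from_network(
    sample: FundusSample,
    od_checkpoint: Checkpoint,
    od_stats: NormStats,
    stride: int = 5,
    macula_center: Optional[tuple[float, float]] = None,
    **predict_kwargs,
) -> anat.AnatomyFit:
    """Anatomy fit from the OD segmentation network's probability map."""
    od_map = anat.segment_od(sample, od_checkpoint, od_stats, stride=stride,
                             **predict_kwargs)
    canonical = resize_to_canonical(sample, od_stats.side)
    return anat.fit_anatomy(canonical, od_map, macula_center=macula_center)


def variant_maps(
    raw_maps: Sequence[ProbabilityMap],
    anatomies: Sequence[anat.AnatomyFit],
    macula_side: int = 80,
) -> dict[str, list[ProbabilityMap]]:
    """The four evaluation variants: raw, +macula mask, +OD mask, +both."""
    out = {"raw": list(raw_maps), "macula_masked": [], "od_masked": [], "both_masked": []}
    for pmap, fit in zip(raw_maps, anatomies):
        out["macula_masked"].append(
            postprocess_map(pmap, fit, od_enabled=False, macula_side=macula_side)
        )
        out["od_masked"].append(
            postprocess_map(pmap, fit, macula_enabled=False, macula_side=macula_side)
        )
        out["both_masked"].append(
            postprocess_map(pmap, fit, macula_side=macula_side)
        )
    return out
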