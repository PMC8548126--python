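"""Reading and writing of fundus images, lesion masks, probability maps and manifests.

Canonical in-memory conventions used throughout the package:

* coordinates are ``(row, col)``, 0-based, origin at the top-left corner;
* images are ``uint8`` arrays of shape ``(H, W, 3)`` with values in [0, 255];
* masks are ``uint8`` arrays of shape ``(H, W)`` containing only {0, 1};
* probability maps are float arrays of shape ``(H, W)`` with values in [0, 1].
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

VALID_SPLITS = ("train", "test")

MANIFEST_COLUMNS = ("id", "image", "lesion_mask", "od_mask", "split")


class ManifestError(ValueError):
    """Raised when a manifest fails validation."""


class SampleError(ValueError):
    """Raised when a sample's files are inconsistent."""


@dataclass
class FundusSample:
    """A fundus photograph with its pixel-level ground truth.

    ``lesion_mask`` marks photocoagulation laser scars (1 = laser mark),
    ``od_mask`` optionally marks the optic disc, and ``macula_center`` is the
    annotated (row, col) of the fovea when known.
    """

    id: str
    image: np.ndarray
    lesion_mask: np.ndarray
    od_mask: Optional[np.ndarray] = None
    macula_center: Optional[tuple[float, float]] = None
    split: str = "train"

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise SampleError(f"sample {self.id!r}: image must be H x W x 3, got {img.shape}")
        for name, mask in (("lesion_mask", self.lesion_mask), ("od_mask", self.od_mask)):
            if mask is None:
                continue
            mask = np.asarray(mask)
            if mask.shape != img.shape[:2]:
                raise SampleError(
                    f"sample {self.id!r}: {name} shape {mask.shape} does not match "
                    f"image shape {img.shape[:2]}"
                )
            vals = np.unique(mask)
            if not np.isin(vals, (0, 1)).all():
                raise SampleError(f"sample {self.id!r}: {name} must be binary, found {vals[:5]}")
        if self.split not in VALID_SPLITS:
            raise SampleError(f"sample {self.id!r}: unknown split {self.split!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class ManifestRecord:
    id: str
    image_path: Path
    lesion_mask_path: Path
    od_mask_path: Optional[Path]
    split: str
    extras: dict = field(default_factory=dict)


@dataclass
class Manifest:
    records: list[ManifestRecord]

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "Manifest":
        return Manifest([r for r in self.records if r.split == split])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass
class ProbabilityMap:
    """Per-pixel probability of the laser-mark class, aligned with its source image."""

    values: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"probability map {self.id!r} must be 2-D, got shape {v.shape}")
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise ValueError(
                f"probability map {self.id!r} has values outside [0, 1]: "
                f"range [{v.min():.4g}, {v.max():.4g}]"
            )
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def load_manifest(path: str | os.PathLike) -> Manifest:
    """Load and validate a CSV manifest.

    The CSV must carry the header columns ``id,image,lesion_mask,od_mask,split``;
    relative paths are resolved against the CSV's own directory.  Extra columns
    (for instance ``macula_row``/``macula_col`` written by the synthetic
    generator) are preserved in each record's ``extras`` dict.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} lacks columns {missing}")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise ManifestError(f"manifest {path} has duplicate ids: {sorted(set(dupes))}")
    bad = sorted(set(df["split"]) - set(VALID_SPLITS))
    if bad:
        raise ManifestError(f"manifest {path} has unknown split tokens: {bad}")

    root = path.parent
    extra_cols = [c for c in df.columns if c not in MANIFEST_COLUMNS]
    records = []
    for row in df.itertuples(index=False):
        rec = row._asdict()

        def resolve(p) -> Optional[Path]:
            if p is None or (isinstance(p, float) and np.isnan(p)) or p == "":
                return None
            p = Path(p)
            p = p if p.is_absolute() else root / p
            if not p.is_file():
                raise FileNotFoundError(f"manifest {path}: referenced file missing: {p}")
            return p

        records.append(
            ManifestRecord(
                id=str(rec["id"]),
                image_path=resolve(rec["image"]),
                lesion_mask_path=resolve(rec["lesion_mask"]),
                od_mask_path=resolve(rec.get("od_mask")),
                split=rec["split"],
                extras={c: rec[c] for c in extra_cols},
            )
        )
    return Manifest(records)


def _read_mask(path: Path, sample_id: str) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        raise SampleError(f"sample {sample_id!r}: mask {path} is not single-channel")
    # >127 threshold tolerates anti-aliased hand annotations on 8-bit input
    return (arr > 127).astype(np.uint8)


def load_sample(record: ManifestRecord) -> FundusSample:
    """Materialize one manifest record into a :class:`FundusSample`."""
    img = np.asarray(Image.open(record.image_path).convert("RGB"))
    lesion = _read_mask(record.lesion_mask_path, record.id)
    if lesion.shape != img.shape[:2]:
        raise SampleError(
            f"sample {record.id!r}: mask shape {lesion.shape} != image shape {img.shape[:2]}"
        )
    od = None
    if record.od_mask_path is not None:
        od = _read_mask(record.od_mask_path, record.id)
    macula = None
    if "macula_row" in record.extras and "macula_col" in record.extras:
        mr, mc = record.extras["macula_row"], record.extras["macula_col"]
        if not (pd.isna(mr) or pd.isna(mc)):
            macula = (float(mr), float(mc))
    return FundusSample(
        id=record.id, image=img, lesion_mask=lesion, od_mask=od,
        macula_center=macula, split=record.split,
    )


def save_probability_map(
    pmap: ProbabilityMap, path: str | os.PathLike, lossless: bool = True
) -> None:
    """Write an 8-bit grayscale PNG rendering of a probability map.

    The PNG stores ``round(255 * p)`` with round-half-up.  When ``lossless``
    is set (the default) a float32 ``.npy`` container is written alongside so
    that downstream ROC evaluation is not limited by 8-bit quantization.
    """
    v = pmap.values
    if v.size and (v.min() < 0.0 or v.max() > 1.0):
        raise ValueError(f"probability map {pmap.id!r} has values outside [0, 1]")
    path = Path(path)
    eight_bit = np.floor(255.0 * v + 0.5).astype(np.uint8)  # round half up
    Image.fromarray(eight_bit, mode="L").save(path)
    if lossless:
        np.save(path.with_suffix(".npy"), v.astype(np.float32))


def load_probability_map(path: str | os.PathLike, map_id: str = "") -> ProbabilityMap:
    """Reload a saved probability map, preferring the lossless container."""
    path = Path(path)
    npy = path.with_suffix(".npy")
    if npy.is_file():
        return ProbabilityMap(np.load(npy).astype(float), id=map_id)
    arr = np.asarray(Image.open(path), dtype=float) / 255.0
    return ProbabilityMap(arr, id=map_id)


def save_sample(sample: FundusSample, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write a sample's image and masks as PNGs; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    img_path = out_dir / f"{sample.id}.png"
    Image.fromarray(sample.image.astype(np.uint8), mode="RGB").save(img_path)
    paths["image"] = img_path
    lesion_path = out_dir / f"{sample.id}_lesion.png"
    Image.fromarray((sample.lesion_mask * 255).astype(np.uint8), mode="L").save(lesion_path)
    paths["lesion_mask"] = lesion_path
    if sample.od_mask is not None:
        od_path = out_dir / f"{sample.id}_od.png"
        Image.fromarray((sample.od_mask * 255).astype(np.uint8), mode="L").save(od_path)
        paths["od_mask"] = od_path
    return paths


def write_manifest(
    rows: Sequence[dict], path: str | os.PathLike, root: Optional[Path] = None
) -> Manifest:
    """Write manifest rows (dicts with at least the standard columns) as CSV and reload."""
    path = Path(path)
    df = pd.DataFrame(list(rows))
    if root is not None:
        for col in ("image", "lesion_mask", "od_mask"):
            if col in df.columns:
                df[col] = [
                    os.path.relpath(p, root) if isinstance(p, (str, Path)) and p else p
                    for p in df[col]
                ]
    df.to_csv(path, index=False)
    return load_manifest(path)
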