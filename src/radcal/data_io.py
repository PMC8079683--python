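"""Manifest and image ingestion, preprocessing, augmentation, batch streaming.

The canonical interchange format is a CSV manifest with header
``image_id,path,patient_id,study_id,region,label,split`` (UTF-8, label in
{0,1}, split in {train, validation, test}).  A convenience importer walks
directory trees in the public MURA layout
(``<split>/XR_<REGION>/patient<id>/study<k>_<positive|negative>/image<j>.png``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize
from scipy.ndimage import rotate as _nd_rotate

log = logging.getLogger(__name__)

REGIONS = ("Elbow", "Finger", "Forearm", "Hand", "Humerus", "Shoulder", "Wrist")
SPLITS = ("train", "validation", "test")
MANIFEST_COLUMNS = ("image_id", "path", "patient_id", "study_id", "region", "label", "split")

TARGET_SIZE = 256


class ManifestError(ValueError):
    """Schema or content violation in a manifest."""


@dataclass(frozen=True)
class ImageRecord:
    image_id: str
    path: str
    patient_id: str
    study_id: str
    region: str
    label: int
    split: str


@dataclass(frozen=True)
class Study:
    study_id: str
    region: str
    views: tuple[ImageRecord, ...]
    label: int

    def __post_init__(self):
        if not self.views:
            raise ManifestError(f"study {self.study_id} has no views")
        for v in self.views:
            if (v.study_id, v.region, v.label) != (self.study_id, self.region, self.label):
                raise ManifestError(
                    f"study {self.study_id}: view {v.image_id} disagrees on "
                    "study_id/region/label")


@dataclass
class Manifest:
    """A table of image records with study grouping and count queries."""

    df: pd.DataFrame
    region_set: tuple[str, ...] = REGIONS

    def __post_init__(self):
        missing = [c for c in MANIFEST_COLUMNS if c not in self.df.columns]
        if missing:
            raise ManifestError(f"manifest missing column(s): {', '.join(missing)}")
        dup = self.df["image_id"].duplicated()
        if dup.any():
            first = self.df.loc[dup, "image_id"].iloc[0]
            raise ManifestError(f"duplicate image_id: {first!r}")
        bad = ~self.df["label"].isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ManifestError(
                f"label outside {{0,1}} in row {row + 1}: {self.df['label'].iloc[row]!r}")
        bad = ~self.df["split"].isin(SPLITS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ManifestError(
                f"unknown split in row {row + 1}: {self.df['split'].iloc[row]!r}")
        bad = ~self.df["region"].isin(self.region_set)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ManifestError(
                f"region not in configured set in row {row + 1}: "
                f"{self.df['region'].iloc[row]!r}")
        # study consistency
        g = self.df.groupby("study_id")[["region", "label", "patient_id"]].nunique()
        bad_studies = g[(g > 1).any(axis=1)]
        if len(bad_studies):
            raise ManifestError(
                f"study {bad_studies.index[0]!r} mixes regions, labels or patients")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[ImageRecord]:
        return [ImageRecord(**{c: row[c] for c in MANIFEST_COLUMNS})
                for row in self.df.to_dict("records")]

    def counts(self, split: str | None = None, region: str | None = None) -> tuple[int, int]:
        """(n_abnormal, n_normal) for the selected slice."""
        d = self.subset(split=split, region=region).df
        return int((d["label"] == 1).sum()), int((d["label"] == 0).sum())

    def count_table(self) -> pd.DataFrame:
        """Rows (split, region) with abnormal/normal counts."""
        t = (self.df.groupby(["split", "region", "label"]).size()
             .unstack("label", fill_value=0))
        for col in (0, 1):
            if col not in t.columns:
                t[col] = 0
        return t.rename(columns={0: "normal", 1: "abnormal"})[["abnormal", "normal"]]

    def subset(self, split: str | None = None, region: str | None = None) -> "Manifest":
        d = self.df
        if split is not None:
            d = d[d["split"] == split]
        if region is not None:
            regions = [region] if isinstance(region, str) else list(region)
            d = d[d["region"].isin(regions)]
        m = object.__new__(Manifest)
        m.df = d.reset_index(drop=True)
        m.region_set = self.region_set
        return m

    def studies(self, split: str | None = None, region: str | None = None) -> list[Study]:
        d = self.subset(split=split, region=region).df
        out = []
        for sid, grp in d.groupby("study_id", sort=True):
            views = tuple(ImageRecord(**{c: r[c] for c in MANIFEST_COLUMNS})
                          for r in grp.to_dict("records"))
            out.append(Study(sid, views[0].region, views, views[0].label))
        return out


def load_manifest(path, region_set: tuple[str, ...] = REGIONS) -> Manifest:
    """Read a CSV manifest, validating schema and content."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"image_id": str, "path": str, "patient_id": str,
                                  "study_id": str, "region": str, "split": str},
                     comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing column(s): {', '.join(missing)}")
    if not pd.api.types.is_integer_dtype(df["label"]):
        coerced = pd.to_numeric(df["label"], errors="coerce")
        bad = coerced.isna() | (coerced != coerced.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ManifestError(f"non-integer label in row {row + 1}")
        df["label"] = coerced.astype(int)
    return Manifest(df[list(MANIFEST_COLUMNS)].copy(), region_set)


def write_manifest(manifest: Manifest, path) -> None:
    manifest.df[list(MANIFEST_COLUMNS)].to_csv(path, index=False)


_MURA_RE = re.compile(
    r"XR_(?P<region>[A-Z]+)[/\\]patient(?P<patient>\w+)[/\\]"
    r"study(?P<study>\d+)_(?P<verdict>\w+)$")
_SPLIT_ALIASES = {"train": "train", "valid": "validation",
                  "validation": "validation", "test": "test"}


def scan_mura_tree(root, on_unknown_region: str = "error") -> Manifest:
    """Import a directory tree in the public MURA layout.

    Folder suffixes other than positive/negative are skipped with a warning;
    unknown region folders either raise (default) or are skipped when
    ``on_unknown_region="skip"``.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(root)
    rows = []
    for img in sorted(root.rglob("*.png")):
        m = _MURA_RE.search(str(img.parent))
        if not m:
            continue
        verdict = m["verdict"].lower()
        if verdict not in ("positive", "negative"):
            log.warning("skipping %s: study folder suffix %r is neither "
                        "positive nor negative", img, m["verdict"])
            continue
        region = m["region"].capitalize()
        if region not in REGIONS:
            if on_unknown_region == "skip":
                log.warning("skipping %s: unknown region %r", img, region)
                continue
            raise ManifestError(f"unknown region folder XR_{m['region']}")
        split = None
        for part in img.relative_to(root).parts:
            if part.lower() in _SPLIT_ALIASES:
                split = _SPLIT_ALIASES[part.lower()]
                break
        if split is None:
            split = "train"
        patient = m["patient"]
        study_id = f"patient{patient}_study{m['study']}"
        rows.append({
            "image_id": f"{study_id}_{img.stem}",
            "path": str(img),
            "patient_id": f"patient{patient}",
            "study_id": study_id,
            "region": region,
            "label": 1 if verdict == "positive" else 0,
            "split": split,
        })
    return Manifest(pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)))


def load_image(path) -> np.ndarray:
    """Read a PNG as a float array in raw [0, 255] scale (luminance for RGB)."""
    with Image.open(path) as im:
        if im.mode not in ("L", "I;16", "I"):
            im = im.convert("L")
        arr = np.asarray(im, dtype=np.float64)
    if arr.max() > 255:  # 16-bit source
        arr = arr * (255.0 / arr.max())
    return arr


def preprocess_image(pixels: np.ndarray, size: int = TARGET_SIZE) -> np.ndarray:
    """Resize to ``size`` x ``size`` and map raw [0, 255] to [0, 1].

    The intensity map is the fixed scaling v/255 (not per-image min-max),
    so constant images stay constant.  Resizing is bilinear without
    aspect-ratio preservation.  Values outside [0, 255] are clamped with a
    warning.  Already resized, already normalized input passes through
    unchanged (idempotence).
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("expected a non-empty 2-D intensity grid")
    if pixels.min() >= 0.0 and pixels.max() <= 1.0:
        out = pixels  # already on [0, 1]
    else:
        if pixels.min() < 0 or pixels.max() > 255:
            log.warning("clamping pixel values outside [0, 255]")
            pixels = np.clip(pixels, 0, 255)
        out = pixels / 255.0
    if out.shape != (size, size):
        out = _sk_resize(out, (size, size), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def sample_augmentation_plan(rng: np.random.Generator) -> list:
    """Draw 1-3 transformations without replacement, in random order.

    Returns a list of ``"hflip"``, ``"vflip"`` or ``("rotate", theta)``
    with theta ~ Uniform(-30, 30) degrees, drawn only when rotation is
    selected so the stream stays reproducible.
    """
    k = int(rng.integers(1, 4))
    ops = rng.permutation(3)[:k]
    plan = []
    for op in ops:
        if op == 0:
            plan.append("hflip")
        elif op == 1:
            plan.append("vflip")
        else:
            plan.append(("rotate", float(rng.uniform(-30.0, 30.0))))
    return plan


def apply_augmentation_plan(pixels: np.ndarray, plan: list) -> np.ndarray:
    """Apply a sampled plan; rotation is bilinear with 0-filled corners."""
    out = np.asarray(pixels, dtype=np.float64)
    for op in plan:
        if op == "hflip":
            out = out[:, ::-1]
        elif op == "vflip":
            out = out[::-1, :]
        else:
            out = _nd_rotate(out, op[1], reshape=False, order=1,
                             mode="constant", cval=0.0)
    return np.clip(np.ascontiguousarray(out), 0.0, 1.0)


def augment_image(pixels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply 1-3 of {horizontal flip, vertical flip, rotation in [-30, 30]deg}.

    The number of transformations is uniform on {1, 2, 3}; they are sampled
    without replacement and applied in the sampled order.  Deterministic
    given the generator state; preserves shape and the [0, 1] range.
    """
    return apply_augmentation_plan(pixels, sample_augmentation_plan(rng))


def default_batch_size(model_tag: str) -> int:
    """32, except 16 for the densely connected model (memory footprint)."""
    return 16 if "dense" in model_tag.lower() else 32


def batch_stream(manifest: Manifest, batch_size: int, rng: np.random.Generator,
                 augment: bool = False, split: str = "train",
                 image_size: int = TARGET_SIZE,
                 with_meta: bool = False) -> Iterator[tuple]:
    """One shuffled epoch over a split, loading one batch of pixels at a time.

    Yields ``(images, labels)`` with images of shape (b, image_size,
    image_size); the last batch may be short.  ``with_meta=True`` appends
    the per-instance region array (used by the weighted loss).
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    d = manifest.subset(split=split).df
    if len(d) == 0:
        raise ManifestError(f"manifest has no records in split {split!r}")
    order = rng.permutation(len(d))
    for start in range(0, len(d), batch_size):
        idx = order[start:start + batch_size]
        rows = d.iloc[idx]
        imgs = np.stack([
            _load_and_prepare(r, rng if augment else None, image_size)
            for r in rows.to_dict("records")])
        labels = rows["label"].to_numpy()
        if with_meta:
            yield imgs, labels, rows["region"].to_numpy()
        else:
            yield imgs, labels


def _load_and_prepare(row: dict, aug_rng: np.random.Generator | None,
                      image_size: int) -> np.ndarray:
    img = preprocess_image(load_image(row["path"]), size=image_size)
    if aug_rng is not None:
        img = augment_image(img, aug_rng)
    return img
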