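"""Seeded generator of radiograph-like multi-view studies and of controlled
prediction tables.

Images are smooth bone-like ridges plus low- and high-frequency noise;
abnormal images additionally carry one of three parametric signal
families — a dark line discontinuity (caricature fracture), a bright
ellipse (implant/hardware) or a high-frequency texture patch (degenerative
roughening) — at a configurable signal-to-noise ratio, with a tight
ground-truth bounding box per lesion.  Prediction tables are drawn from a
binormal score model whose analytic AUC is a closed form of the
separability parameter, so evaluation and ensembling can be tested without
any training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .data_io import MANIFEST_COLUMNS, Manifest, SPLITS

SIGNAL_FAMILIES = ("line_discontinuity", "bright_implant", "texture_roughening")

NOISE_SIGMA = 0.05  # pixel-noise scale against which snr is defined


@dataclass(frozen=True)
class RegionSignalSpec:
    region: str
    signal_family: str
    snr: float
    lesion_size_range: tuple[int, int] = (8, 16)

    def __post_init__(self):
        if self.signal_family not in SIGNAL_FAMILIES:
            raise ValueError(f"unknown signal family {self.signal_family!r}")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class GeneratorConfig:
    region_specs: tuple[RegionSignalSpec, ...]
    # split -> (n_abnormal, n_normal) applied to every region
    split_counts: dict = field(default_factory=lambda: {
        "train": (40, 60), "validation": (20, 30), "test": (20, 30)})
    views_per_study: tuple[int, int] = (1, 4)
    image_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if not self.region_specs:
            raise ValueError("at least one region required")
        for split, (na, nn_) in self.split_counts.items():
            if split not in SPLITS:
                raise ValueError(f"unknown split {split!r}")
            if na < 0 or nn_ < 0:
                raise ValueError("counts must be non-negative")
        for spec in self.region_specs:
            if spec.lesion_size_range[1] >= self.image_size:
                raise ValueError("lesion does not fit inside the image")


def desk_scale_config(seed: int = 0, image_size: int = 64) -> GeneratorConfig:
    """7 regions cycling through the three signal families."""
    from .data_io import REGIONS
    specs = tuple(RegionSignalSpec(r, SIGNAL_FAMILIES[i % 3], snr=4.0)
                  for i, r in enumerate(REGIONS))
    return GeneratorConfig(specs, image_size=image_size, seed=seed)


@dataclass
class SyntheticDataset:
    manifest: Manifest
    root: Path
    boxes: pd.DataFrame  # columns: image_id, x0, y0, x1, y1 (half-open)

    def box_for(self, image_id: str) -> tuple[int, int, int, int] | None:
        row = self.boxes[self.boxes["image_id"] == image_id]
        if len(row) == 0:
            return None
        r = row.iloc[0]
        return int(r["x0"]), int(r["y0"]), int(r["x1"]), int(r["y1"])


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth bone-like ridge plus correlated and white noise, in [0, 1]."""
    x = np.arange(size)
    cx = rng.uniform(0.3, 0.7) * size
    width = rng.uniform(0.10, 0.18) * size
    ridge = 0.40 * np.exp(-((x - cx) / width) ** 2)
    # base level 0.35 leaves headroom for dark lesions against the off-bone
    # background; correlated noise stays below the snr>=3 lesion amplitude
    img = 0.35 + ridge[None, :] * np.ones((size, 1))
    img = img + 0.02 * gaussian_filter(rng.standard_normal((size, size)), sigma=3)
    img = img + NOISE_SIGMA * rng.standard_normal((size, size))
    return np.clip(img, 0.0, 1.0)


def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def plant_abnormality(image: np.ndarray, spec: RegionSignalSpec,
                      rng: np.random.Generator,
                      params: dict | None = None) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Inject the region's signal; returns (image, tight bounding box).

    The box is half-open pixel coordinates (x0, y0, x1, y1) tightly
    containing every modified pixel.  ``params`` fixes lesion geometry
    (used to correlate views of one study).  Output stays in [0, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    size = image.shape[0]
    lo, hi = spec.lesion_size_range
    if hi >= size:
        raise ValueError("lesion larger than image")
    if params is None:
        params = {
            "diameter": float(rng.uniform(lo, hi)),
            "cy": float(rng.uniform(hi, size - hi)),
            "cx": float(rng.uniform(hi, size - hi)),
            "theta": float(rng.uniform(0, np.pi)),
        }
    d, cy, cx, theta = params["diameter"], params["cy"], params["cx"], params["theta"]
    amp = spec.snr * NOISE_SIGMA

    if spec.signal_family == "bright_implant":
        mask = _ellipse_mask(size, cy, cx, d / 2.0, d / 3.0, theta)
        delta = amp * mask.astype(float)
    elif spec.signal_family == "line_discontinuity":
        mask = _ellipse_mask(size, cy, cx, d / 2.0, max(d / 5.0, 1.5), theta)
        # thin structures lose amplitude to any blur; 1.3 calibrates the
        # family to the same matched-filter detectability as the implant
        delta = -1.3 * amp * mask.astype(float)
    else:  # texture_roughening
        half = d / 2.0
        yy, xx = np.mgrid[0:size, 0:size]
        mask = (np.abs(yy - cy) <= half) & (np.abs(xx - cx) <= half)
        noise = rng.standard_normal((size, size))
        rough = noise - gaussian_filter(noise, sigma=1.5)
        delta = amp * 1.5 * rough * mask
    out = np.clip(image + delta, 0.0, 1.0)
    ys, xs = np.nonzero(mask)
    box = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
    return out, box


def _jitter(params: dict, rng: np.random.Generator, size: int) -> dict:
    """Small per-view perturbation of shared lesion geometry."""
    return {
        "diameter": params["diameter"],
        "cy": float(np.clip(params["cy"] + rng.uniform(-2, 2), 0, size - 1)),
        "cx": float(np.clip(params["cx"] + rng.uniform(-2, 2), 0, size - 1)),
        "theta": float(params["theta"] + rng.uniform(-0.2, 0.2)),
    }


def generate_dataset(config: GeneratorConfig, out_dir) -> SyntheticDataset:
    """Render studies to PNG, write manifest.csv and boxes.csv; seeded."""
    total = sum(na + nn_ for na, nn_ in config.split_counts.values())
    if total * len(config.region_specs) == 0:
        raise ValueError("configuration yields zero images")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    vmin, vmax = config.views_per_study
    rows, box_rows = [], []
    for spec in config.region_specs:
        for split in SPLITS:
            if split not in config.split_counts:
                continue
            for label, n_images in zip((1, 0), config.split_counts[split]):
                remaining = n_images
                study_i = 0
                while remaining > 0:
                    n_views = min(int(rng.integers(vmin, vmax + 1)), remaining)
                    study_id = f"{spec.region}_{split}_{'abn' if label else 'nrm'}_{study_i:04d}"
                    lesion = {
                        "diameter": float(rng.uniform(*spec.lesion_size_range)),
                        "cy": float(rng.uniform(spec.lesion_size_range[1],
                                                config.image_size - spec.lesion_size_range[1])),
                        "cx": float(rng.uniform(spec.lesion_size_range[1],
                                                config.image_size - spec.lesion_size_range[1])),
                        "theta": float(rng.uniform(0, np.pi)),
                    }
                    for v in range(n_views):
                        image_id = f"{study_id}_v{v}"
                        img = _background(config.image_size, rng)
                        if label == 1:
                            img, box = plant_abnormality(
                                img, spec, rng,
                                params=_jitter(lesion, rng, config.image_size))
                            box_rows.append({"image_id": image_id, "x0": box[0],
                                             "y0": box[1], "x1": box[2], "y1": box[3]})
                        rel = f"images/{image_id}.png"
                        Image.fromarray((img * 255).round().astype(np.uint8)).save(
                            out_dir / rel)
                        rows.append({
                            "image_id": image_id, "path": str(out_dir / rel),
                            "patient_id": study_id, "study_id": study_id,
                            "region": spec.region, "label": label, "split": split,
                        })
                    remaining -= n_views
                    study_i += 1
    manifest = Manifest(pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)))
    boxes = pd.DataFrame(box_rows, columns=["image_id", "x0", "y0", "x1", "y1"])
    from .data_io import write_manifest
    write_manifest(manifest, out_dir / "manifest.csv")
    boxes.to_csv(out_dir / "boxes.csv", index=False)
    return SyntheticDataset(manifest, out_dir, boxes)


# ---------------------------------------------------------------------------
# controlled prediction tables (binormal score model)

def analytic_auc(separability: float) -> float:
    """AUC of the equal-variance binormal model: Phi(d / sqrt(2))."""
    return float(norm.cdf(separability / np.sqrt(2.0)))


def separability_for_auc(auc: float) -> float:
    """Inverse of :func:`analytic_auc`."""
    if not 0.0 < auc < 1.0:
        raise ValueError("auc must lie strictly between 0 and 1")
    return float(np.sqrt(2.0) * norm.ppf(auc))


def synth_prediction_table(skill: dict, n_studies: int, seed: int = 0,
                           prevalence: float = 0.5):
    """Draw a PredictionTable from class-conditional binormal scores.

    ``skill`` maps (model_id, region) -> separability d >= 0; negative
    scores ~ N(0,1), positive ~ N(d,1); probabilities are the logistic of
    the score, which preserves the analytic AUC Phi(d/sqrt(2)).  Labels
    take exactly round(prevalence * n) positives per region.
    """
    from .evaluation import PredictionTable

    if n_studies < 4:
        raise ValueError("need at least 2 studies per class per region")
    n_pos = int(round(prevalence * n_studies))
    n_neg = n_studies - n_pos
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 studies per class per region")
    for d in skill.values():
        if d < 0:
            raise ValueError("separability must be >= 0")
    regions = sorted({r for _, r in skill})
    models = sorted({m for m, _ in skill})
    for m in models:
        for r in regions:
            if (m, r) not in skill:
                raise ValueError(f"missing skill entry for ({m!r}, {r!r})")
    rng = np.random.default_rng(seed)
    rows = []
    for region in regions:
        labels = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
        base = rng.standard_normal(n_studies)  # shared noise across models
        for mid in models:
            d = skill[(mid, region)]
            scores = base + d * (labels == 1)
            probs = 1.0 / (1.0 + np.exp(-scores))
            for i in range(n_studies):
                rows.append({
                    "study_id": f"{region}_s{i:05d}", "region": region,
                    "true_label": int(labels[i]), "model_id": mid,
                    "prob": float(probs[i]),
                })
    return PredictionTable(pd.DataFrame(rows))
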