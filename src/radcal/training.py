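"""Class-weighted loss, training loop, checkpointing, per-region fine-tuning.

The loss is cross-entropy with per-region class weights inversely
proportional to the class counts of the training split:

    w0_t = |A_t| / (|N_t| + |A_t|)      (weight for normal instances)
    w1_t = |N_t| / (|N_t| + |A_t|)      (weight for abnormal instances)

so the minority class always carries the larger weight and w0 + w1 = 1 per
region.  Optimization is Adam (beta1=0.9, beta2=0.999, lr=0.001 by
default); training stops at ``max_epochs`` or when the relative training
loss improvement stays below ``min_delta`` for ``patience`` consecutive
epochs, and the returned model is the epoch checkpoint with the best
validation metric.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from . import nn
from .architectures import ArchitectureSpec, TrainableModel, build_model
from .data_io import Manifest, batch_stream
from .evaluation import roc_auc, study_probability

log = logging.getLogger(__name__)

PROB_CLIP = 1e-7


@dataclass
class TrainConfig:
    beta1: float = 0.9
    beta2: float = 0.999
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    min_delta: float = 1e-4
    patience: int = 5
    checkpoint_metric: str = "auc"
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1, beta2 must lie in (0, 1)")
        if self.max_epochs < 0:
            # 0 is allowed for fine-tuning's "copy weights, no training" case
            raise ValueError("max_epochs must be >= 0")


@dataclass(frozen=True)
class ClassWeights:
    region: str
    w0: float  # weight for normal (label 0) instances
    w1: float  # weight for abnormal (label 1) instances

    def __post_init__(self):
        if not np.isclose(self.w0 + self.w1, 1.0, atol=1e-12):
            raise ValueError("class weights must sum to 1")


def compute_class_weights(manifest: Manifest, region: str, split: str = "train") -> ClassWeights:
    """Per-region weights from the training-split class counts (exact rationals)."""
    n_abnormal, n_normal = manifest.counts(split=split, region=region)
    if n_abnormal == 0 or n_normal == 0:
        raise ValueError(
            f"region {region!r} has an empty class in split {split!r} "
            f"(abnormal={n_abnormal}, normal={n_normal}); weighting undefined")
    total = n_abnormal + n_normal
    w0 = Fraction(n_abnormal, total)
    w1 = Fraction(n_normal, total)
    return ClassWeights(region, float(w0), float(w1))


def weighted_cross_entropy(probs, labels, weights: dict[str, ClassWeights] | None,
                           regions=None, reduction: str = "mean") -> float:
    """Region-weighted binary cross-entropy.

    ``weights`` maps region -> ClassWeights; ``regions`` gives each
    instance's region tag.  With ``weights=None`` (w0 = w1 = 1) this is the
    standard unweighted cross-entropy.  Probabilities are clipped to
    [1e-7, 1 - 1e-7] before the logarithms.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels length mismatch")
    w0, w1 = _instance_weights(labels.shape[0], weights, regions)
    p = np.clip(probs, PROB_CLIP, 1.0 - PROB_CLIP)
    terms = -(w1 * labels * np.log(p) + w0 * (1.0 - labels) * np.log(1.0 - p))
    return float(terms.mean() if reduction == "mean" else terms.sum())


def _instance_weights(n, weights, regions):
    if weights is None:
        return np.ones(n), np.ones(n)
    if regions is None:
        raise ValueError("per-region weights require per-instance region tags")
    regions = np.asarray(regions)
    if regions.shape[0] != n:
        raise ValueError("regions length mismatch")
    w0 = np.empty(n)
    w1 = np.empty(n)
    for i, r in enumerate(regions):
        cw = weights[r]
        w0[i], w1[i] = cw.w0, cw.w1
    return w0, w1


def _loss_grad(probs, labels, w0, w1):
    """d(mean weighted CE)/d(prob), evaluated on clipped probabilities."""
    p = np.clip(probs, PROB_CLIP, 1.0 - PROB_CLIP)
    n = len(p)
    return (-w1 * labels / p + w0 * (1.0 - labels) / (1.0 - p)) / n


@dataclass
class TrainedModel:
    model: TrainableModel
    history: pd.DataFrame  # columns: epoch, train_loss, val_metric
    best_epoch: int
    config: TrainConfig
    class_weights: dict[str, ClassWeights]
    trained_regions: tuple[str, ...]  # provenance: regions in the training data

    def predict(self, images) -> np.ndarray:
        return self.model.forward(images, training=False)


def train_model(spec: ArchitectureSpec, manifest: Manifest, config: TrainConfig,
                region_filter=None, model: TrainableModel | None = None) -> TrainedModel:
    """Train (or continue training) a model on the manifest's train split.

    ``region_filter`` restricts training and validation to a region subset.
    ``model`` continues from existing weights (used by fine-tuning);
    otherwise a fresh model is built with seeded initialization.  The
    returned model carries the weights of the epoch with the best
    validation ``checkpoint_metric`` (study-level).
    """
    sub = manifest.subset(region=region_filter) if region_filter is not None else manifest
    if len(sub.subset(split="train")) == 0:
        raise ValueError("empty training split")
    train_regions = tuple(sorted(sub.subset(split="train").df["region"].unique()))
    weights = {r: compute_class_weights(sub, r) for r in train_regions}

    if model is None:
        model = build_model(spec, seed=config.seed)
    image_size = spec.input_shape[0]
    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  beta1=config.beta1, beta2=config.beta2)

    history = []
    best_metric = -np.inf
    best_epoch = -1
    best_state = model.get_state()
    best_loss = np.inf
    stale = 0
    for epoch in range(config.max_epochs):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, epoch]))
        losses = []
        for imgs, labels, regions in batch_stream(
                sub, config.batch_size, rng, augment=config.augment,
                split="train", image_size=image_size, with_meta=True):
            probs = model.forward(imgs, training=True)
            w0, w1 = _instance_weights(len(labels), weights, regions)
            losses.append(weighted_cross_entropy(probs, labels, weights, regions))
            opt.zero_grad()
            model.backward(_loss_grad(probs, labels.astype(float), w0, w1))
            opt.step()
        train_loss = float(np.mean(losses))

        val_metric = _validation_metric(model, sub, config.checkpoint_metric, image_size)
        history.append({"epoch": epoch, "train_loss": train_loss, "val_metric": val_metric})
        # ties go to the later epoch: the training loss keeps improving, so
        # among equal validation scores the most-trained weights win
        if np.isfinite(val_metric) and val_metric >= best_metric:
            best_metric = val_metric
            best_epoch = epoch
            best_state = model.get_state()

        # early stopping on training-loss convergence
        if (best_loss - train_loss) / max(best_loss, PROB_CLIP) < config.min_delta:
            stale += 1
        else:
            stale = 0
        best_loss = min(best_loss, train_loss)
        if stale >= config.patience:
            log.info("early stop at epoch %d (loss converged)", epoch)
            break

    if best_epoch < 0:
        best_epoch = len(history) - 1
        best_state = model.get_state()
    model.set_state(best_state)
    return TrainedModel(model, pd.DataFrame(history), best_epoch, config,
                        weights, train_regions)


def _validation_metric(model: TrainableModel, manifest: Manifest,
                       metric: str, image_size: int) -> float:
    try:
        probs, labels = predict_study_split(model, manifest, "validation", image_size)
    except Exception:
        return np.nan
    if len(probs) == 0:
        return np.nan
    if metric == "auc":
        try:
            return roc_auc(probs, labels)
        except ValueError:
            return np.nan
    if metric == "accuracy":
        return float(((probs >= 0.5).astype(int) == labels).mean())
    raise ValueError(f"unknown checkpoint metric {metric!r}")


def predict_image_probs(model: TrainableModel, manifest: Manifest, split: str,
                        image_size: int, batch_size: int = 64) -> pd.DataFrame:
    """Per-image positive-class probabilities for one split (no shuffling)."""
    from .data_io import load_image, preprocess_image
    d = manifest.subset(split=split).df
    rows = []
    for start in range(0, len(d), batch_size):
        chunk = d.iloc[start:start + batch_size]
        imgs = np.stack([preprocess_image(load_image(p), size=image_size)
                         for p in chunk["path"]])
        probs = model.forward(imgs, training=False)
        for (_, r), p in zip(chunk.iterrows(), probs):
            rows.append({"image_id": r["image_id"], "study_id": r["study_id"],
                         "region": r["region"], "true_label": int(r["label"]),
                         "prob": float(p)})
    return pd.DataFrame(rows, columns=["image_id", "study_id", "region",
                                       "true_label", "prob"])


def predict_study_split(model: TrainableModel, manifest: Manifest, split: str,
                        image_size: int) -> tuple[np.ndarray, np.ndarray]:
    """(study probabilities, study labels) for one split."""
    img = predict_image_probs(model, manifest, split, image_size)
    if len(img) == 0:
        return np.array([]), np.array([], dtype=int)
    g = img.groupby("study_id", sort=True)
    probs = np.array([study_probability(list(grp["prob"])) for _, grp in g])
    labels = np.array([int(grp["true_label"].iloc[0]) for _, grp in g])
    return probs, labels


def fine_tune_region(overall: TrainedModel, manifest: Manifest, region: str,
                     config: TrainConfig) -> TrainedModel:
    """Continue training the overall model on one region's records only.

    The new model starts from the overall model's weights; with
    ``max_epochs=0`` it is an exact copy.  Checkpointing uses the region's
    validation subset.
    """
    if region not in set(manifest.df["region"]):
        raise ValueError(f"region {region!r} absent from manifest")
    model = copy.deepcopy(overall.model)
    if config.max_epochs == 0:
        return TrainedModel(model, pd.DataFrame(
            columns=["epoch", "train_loss", "val_metric"]), -1, config,
            overall.class_weights, (region,))
    return train_model(overall.model.spec, manifest, config,
                       region_filter=region, model=model)
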