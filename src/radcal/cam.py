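"""Class activation maps over the final convolutional feature maps.

Two weighting schemes sit behind one operation: when the model's head is
global-average-pooling into a single logistic unit, channel weights are the
classifier weights (classic CAM); otherwise the weights are the spatially
averaged gradients of the class score at the feature tap (gradient-weighted
activation mapping).  The combined map is rectified, bilinearly upsampled
to the input extent and min-max normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .architectures import TrainableModel


@dataclass
class CAMHeatmap:
    grid: np.ndarray          # (H, W) in [0, 1], same extent as the input
    source_image_id: str
    predicted_prob: float
    method: str               # "classifier_weights" | "gradient"


def compute_cam(model: TrainableModel, image: np.ndarray, target_class: int = 1,
                image_id: str = "") -> CAMHeatmap:
    """Heatmap of the evidence for ``target_class`` on one preprocessed image."""
    if not hasattr(model, "feature_tap") or model.tap < 0:
        raise ValueError("model does not expose a feature tap")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected one 2-D preprocessed image")

    head_w = model.head_weights()
    if head_w is not None:
        feats = model.feature_tap(image[None])          # (1, c, h, w)
        weights = head_w if target_class == 1 else -head_w
        method = "classifier_weights"
    else:
        feats, grads = model.grad_at_tap(image[None], target_class)
        weights = grads[0].mean(axis=(1, 2))            # (c,)
        method = "gradient"
    prob = float(model.forward(image[None])[0])

    raw = np.tensordot(weights, feats[0], axes=([0], [0]))  # (h, w)
    raw = np.maximum(raw, 0.0)                              # evidence *for* the class
    up = _sk_resize(raw, image.shape, order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
    lo, hi = float(up.min()), float(up.max())
    grid = np.zeros_like(up) if hi - lo < 1e-12 else (up - lo) / (hi - lo)
    return CAMHeatmap(grid, image_id, prob, method)


def overlay(image: np.ndarray, heatmap: CAMHeatmap, alpha: float = 0.4,
            cmap: str = "jet") -> np.ndarray:
    """Blend the grayscale image with the colormapped heatmap.

    out = (1 - alpha) * gray + alpha * colormap(heat), RGB float in [0, 1].
    """
    import matplotlib
    image = np.asarray(image, dtype=np.float64)
    if image.shape != heatmap.grid.shape:
        raise ValueError("image and heatmap shapes differ")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    gray = np.repeat(image[:, :, None], 3, axis=2)
    colors = matplotlib.colormaps[cmap](heatmap.grid)[:, :, :3]
    return (1.0 - alpha) * gray + alpha * colors


def save_cam_png(image: np.ndarray, heatmap: CAMHeatmap, path,
                 alpha: float = 0.4) -> None:
    """Write a side-by-side (original | overlay) 8-bit PNG, plus the raw
    heatmap as a 16-bit PNG next to it."""
    from PIL import Image

    blend = overlay(image, heatmap, alpha)
    gray = np.repeat(np.asarray(image)[:, :, None], 3, axis=2)
    panel = np.concatenate([gray, blend], axis=1)
    Image.fromarray((np.clip(panel, 0, 1) * 255).astype(np.uint8)).save(path)
    raw16 = (np.clip(heatmap.grid, 0, 1) * 65535).astype(np.uint16)
    raw_path = str(path).rsplit(".", 1)[0] + "_heatmap.png"
    Image.fromarray(raw16).save(raw_path)
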