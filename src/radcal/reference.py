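"""Published statistics for the public MURA musculoskeletal radiograph
benchmark, used as worked-example inputs by the test-suite and the
acceptance report.

``MURA_IMAGE_COUNTS`` gives the (abnormal, normal) image counts per
anatomical region and split as published with the dataset release.
``BENCHMARK_VALIDATION_METRICS`` and ``BENCHMARK_OVERALL_TEST_SCORES``
are the published validation/test scores of the three baseline networks
and the two ensembles on that benchmark; they serve as inputs to the
learner-designation rule and the percent-change computation, not as
values this package claims to reproduce at desk scale.
"""

from __future__ import annotations

import pandas as pd

# (abnormal, normal) per region per split
MURA_IMAGE_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "Elbow":    {"train": (1734, 2584), "validation": (272, 341), "test": (230, 235)},
    "Finger":   {"train": (1710, 2750), "validation": (258, 388), "test": (247, 214)},
    "Forearm":  {"train": (583, 1042),  "validation": (78, 122),  "test": (151, 150)},
    "Hand":     {"train": (1287, 3549), "validation": (197, 510), "test": (189, 271)},
    "Humerus":  {"train": (514, 593),   "validation": (85, 80),   "test": (140, 148)},
    "Shoulder": {"train": (3627, 3673), "validation": (541, 538), "test": (278, 285)},
    "Wrist":    {"train": (3489, 4993), "validation": (498, 772), "test": (295, 364)},
}

MURA_TOTAL_IMAGES = 40_005

# validation-split (auc, accuracy, kappa) per model per region for the three
# baseline networks — the inputs to the 2-of-3 designation rule
BENCHMARK_VALIDATION_METRICS = pd.DataFrame(
    [
        # model_id, region, auc, accuracy, kappa
        ("convnet", "Elbow", 0.90, 0.85, 0.73),
        ("convnet", "Finger", 0.90, 0.83, 0.64),
        ("convnet", "Forearm", 0.85, 0.84, 0.64),
        ("convnet", "Hand", 0.84, 0.78, 0.52),
        ("convnet", "Humerus", 0.91, 0.83, 0.68),
        ("convnet", "Shoulder", 0.84, 0.79, 0.58),
        ("convnet", "Wrist", 0.92, 0.87, 0.77),
        ("resnet", "Elbow", 0.91, 0.84, 0.67),
        ("resnet", "Finger", 0.93, 0.87, 0.68),
        ("resnet", "Forearm", 0.88, 0.85, 0.67),
        ("resnet", "Hand", 0.86, 0.82, 0.60),
        ("resnet", "Humerus", 0.96, 0.90, 0.85),
        ("resnet", "Shoulder", 0.89, 0.84, 0.71),
        ("resnet", "Wrist", 0.96, 0.91, 0.80),
        ("densenet", "Elbow", 0.93, 0.88, 0.80),
        ("densenet", "Finger", 0.92, 0.84, 0.65),
        ("densenet", "Forearm", 0.90, 0.86, 0.70),
        ("densenet", "Hand", 0.85, 0.82, 0.59),
        ("densenet", "Humerus", 0.95, 0.88, 0.75),
        ("densenet", "Shoulder", 0.86, 0.82, 0.63),
        ("densenet", "Wrist", 0.95, 0.89, 0.77),
    ],
    columns=["model_id", "region", "auc", "accuracy", "kappa"],
)

# the published designation on that benchmark
BENCHMARK_DESIGNATION = {
    "Elbow": "densenet", "Finger": "resnet", "Forearm": "densenet",
    "Hand": "resnet", "Humerus": "resnet", "Shoulder": "resnet",
    "Wrist": "resnet",
}

# overall test scores of the baseline and the calibrated ensemble
BENCHMARK_OVERALL_TEST_SCORES = {
    "convnet":    {"auc": 0.88, "accuracy": 0.82, "precision": 0.86,
                   "recall": 0.72, "kappa": 0.63},
    "calibrated": {"auc": 0.93, "accuracy": 0.87, "precision": 0.93,
                   "recall": 0.81, "kappa": 0.74},
}


def mura_count_manifest() -> pd.DataFrame:
    """A manifest data frame with one placeholder row per published image,
    carrying the region/label/split bookkeeping of the benchmark."""
    rows = []
    for region, splits in MURA_IMAGE_COUNTS.items():
        for split, (n_ab, n_nm) in splits.items():
            for label, n in ((1, n_ab), (0, n_nm)):
                for i in range(n):
                    sid = f"{region}_{split}_{label}_{i}"
                    rows.append((sid, f"{sid}.png", sid, sid, region, label, split))
    return pd.DataFrame(rows, columns=[
        "image_id", "path", "patient_id", "study_id", "region", "label", "split"])
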