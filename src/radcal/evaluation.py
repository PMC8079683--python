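"""Study-level decisioning, the five evaluation metrics, and delta tables.

A study's abnormality probability is the arithmetic mean of its views'
positive-class probabilities; the decision thresholds that mean at 0.5
(boundary inclusive).  Metrics: ROC-AUC (Mann-Whitney, ties at half
credit), accuracy, precision, recall, and Cohen's kappa.  Percentage
changes versus a baseline model are reported as integer percent,
rounded half away from zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

METRICS = ("auc", "accuracy", "precision", "recall", "kappa")


@dataclass
class PredictionTable:
    """Long-format study-level predictions.

    ``df`` columns: study_id, region, true_label, model_id, prob — one row
    per (study, model).  Optionally image-level rows can be aggregated in
    via :meth:`from_image_probs`.
    """

    df: pd.DataFrame

    REQUIRED = ("study_id", "region", "true_label", "model_id", "prob")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"prediction table missing column(s): {missing}")
        p = self.df["prob"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if self.df.duplicated(["study_id", "model_id"]).any():
            raise ValueError("one row per (study_id, model_id) required")

    @property
    def model_ids(self) -> list[str]:
        return sorted(self.df["model_id"].unique())

    @property
    def regions(self) -> list[str]:
        return sorted(self.df["region"].unique())

    @staticmethod
    def from_image_probs(image_df: pd.DataFrame, model_id: str) -> "PredictionTable":
        """Aggregate per-image probabilities (mean per study)."""
        g = image_df.groupby("study_id", sort=True).agg(
            region=("region", "first"), true_label=("true_label", "first"),
            prob=("prob", "mean")).reset_index()
        g["model_id"] = model_id
        return PredictionTable(g)

    def concat(self, other: "PredictionTable") -> "PredictionTable":
        return PredictionTable(pd.concat([self.df, other.df], ignore_index=True))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "PredictionTable":
        return PredictionTable(pd.read_csv(path, comment="#"))


@dataclass
class MetricReport:
    """(model_id, scope) -> the five metrics; scope is 'overall' or a region."""

    df: pd.DataFrame  # columns: model_id, scope, auc, accuracy, precision, recall, kappa

    def value(self, model_id: str, metric: str, scope: str = "overall") -> float:
        row = self.df[(self.df["model_id"] == model_id) & (self.df["scope"] == scope)]
        if len(row) != 1:
            raise KeyError((model_id, scope))
        return float(row[metric].iloc[0])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class DeltaTable:
    """(model_id, metric) -> integer percent change vs the baseline model."""

    df: pd.DataFrame  # columns: model_id, metric, delta_percent
    baseline: str

    def value(self, model_id: str, metric: str) -> int:
        row = self.df[(self.df["model_id"] == model_id) & (self.df["metric"] == metric)]
        if len(row) != 1:
            raise KeyError((model_id, metric))
        return int(row["delta_percent"].iloc[0])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def study_probability(view_probs) -> float:
    """Mean positive-class probability over a study's views."""
    view_probs = list(view_probs)
    if not view_probs:
        raise ValueError("study has no view probabilities")
    return float(np.mean(view_probs))


def classify_study(prob: float, threshold: float = 0.5) -> int:
    """1 iff prob >= threshold (boundary inclusive)."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    return int(prob >= threshold)


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels length mismatch")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_metrics(preds, labels) -> tuple[float, float, float]:
    """(accuracy, precision, recall); precision is 0 (with a warning) when
    there are no positive predictions, recall 0 when there are no positives."""
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.shape != labels.shape or preds.size == 0:
        raise ValueError("preds and labels must be equal-length and non-empty")
    tp = int(((preds == 1) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    accuracy = (tp + tn) / preds.size
    if tp + fp == 0:
        log.warning("no positive predictions; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = 0.0 if tp + fn == 0 else tp / (tp + fn)
    return float(accuracy), float(precision), float(recall)


def cohens_kappa(preds, labels) -> float:
    """kappa = (p_o - p_e) / (1 - p_e) with chance agreement from marginals."""
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.shape != labels.shape or preds.size == 0:
        raise ValueError("preds and labels must be equal-length and non-empty")
    n = preds.size
    p_o = float((preds == labels).mean())
    p_pos_a = float((preds == 1).mean())
    p_pos_b = float((labels == 1).mean())
    p_e = p_pos_a * p_pos_b + (1 - p_pos_a) * (1 - p_pos_b)
    if np.isclose(p_e, 1.0):
        if np.isclose(p_o, 1.0):
            return 1.0
        raise ValueError("chance agreement is 1 with imperfect agreement; kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def percent_change(p_m: float, p_base: float) -> int:
    """100 * (p_m - p_base) / p_base, rounded half away from zero to int."""
    if p_base <= 0:
        raise ValueError("baseline score must be positive")
    x = 100.0 * (p_m - p_base) / p_base
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def _metric_row(probs: np.ndarray, labels: np.ndarray, threshold: float) -> dict:
    preds = (probs >= threshold).astype(int)
    if len(np.unique(labels)) < 2:
        log.warning("single-class scope: AUC and kappa undefined")
        auc = np.nan
        kappa = np.nan
    else:
        auc = roc_auc(probs, labels)
        kappa = cohens_kappa(preds, labels)
    accuracy, precision, recall = confusion_metrics(preds, labels)
    return {"auc": auc, "accuracy": accuracy, "precision": precision,
            "recall": recall, "kappa": kappa}


def evaluate(table: PredictionTable, baseline: str | None = None,
             threshold: float = 0.5) -> tuple[MetricReport, DeltaTable | None]:
    """Per-model metrics for 'overall' and each region, plus deltas vs baseline.

    Scopes with a single class get NaN AUC/kappa (reported, not dropped).
    The delta table compares overall scores; the baseline row is all zeros.
    """
    model_ids = table.model_ids
    if baseline is not None and baseline not in model_ids:
        raise ValueError(f"unknown baseline model {baseline!r}")
    rows = []
    for mid in model_ids:
        d = table.df[table.df["model_id"] == mid]
        scopes = [("overall", d)] + [(r, d[d["region"] == r]) for r in table.regions]
        for scope, sd in scopes:
            m = _metric_row(sd["prob"].to_numpy(), sd["true_label"].to_numpy(), threshold)
            rows.append({"model_id": mid, "scope": scope, **m})
    report = MetricReport(pd.DataFrame(rows))

    delta = None
    if baseline is not None:
        drows = []
        for mid in model_ids:
            for metric in METRICS:
                pb = report.value(baseline, metric)
                pm = report.value(mid, metric)
                if mid == baseline:
                    d = 0
                elif np.isfinite(pm) and np.isfinite(pb) and pb > 0:
                    d = percent_change(pm, pb)
                else:  # undefined score or zero baseline: report, don't drop
                    d = np.nan
                drows.append({"model_id": mid, "metric": metric, "delta_percent": d})
        delta = DeltaTable(pd.DataFrame(drows), baseline)
    return report, delta


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """(fpr, tpr, threshold) rows for CSV export."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos = max(int((y == 1).sum()), 1)
    n_neg = max(int((y == 0).sum()), 1)
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    last = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    rows = [{"fpr": 0.0, "tpr": 0.0, "threshold": np.inf}]
    for i in last:
        rows.append({"fpr": fps[i] / n_neg, "tpr": tps[i] / n_pos, "threshold": s[i]})
    return pd.DataFrame(rows)
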