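"""Averaging ensemble and the calibrated per-region learner designation rule.

Two combiners are provided:

* :func:`average_predict` — the traditional two-model ensemble that
  averages positive-class probabilities and predicts abnormal when their
  sum reaches 1 (equivalently, when the mean reaches 0.5).
* :func:`designate_learners` / :func:`calibrated_predict` — the calibrated
  rule: per anatomical region, designate the candidate model that is best
  on the validation split in at least two of {AUC, accuracy, kappa}, then
  route every study of that region to its designated (fine-tuned) model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import Study
from .evaluation import PredictionTable, classify_study, study_probability

log = logging.getLogger(__name__)

DESIGNATION_METRICS = ("auc", "accuracy", "kappa")
WIN_TOLERANCE = 1e-9


@dataclass
class SelectionTable:
    """region -> designated model, plus the metric triplets used to decide."""

    designated: dict[str, str]
    provenance: pd.DataFrame  # columns: region, model_id, auc, accuracy, kappa

    def model_for(self, region: str) -> str:
        if region not in self.designated:
            raise KeyError(f"no designated learner for region {region!r}")
        return self.designated[region]

    def to_csv(self, path) -> None:
        df = self.provenance.copy()
        df["designated"] = [self.designated[r] == m
                            for r, m in zip(df["region"], df["model_id"])]
        df.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "SelectionTable":
        df = pd.read_csv(path, comment="#")
        designated = {r: grp.loc[grp["designated"], "model_id"].iloc[0]
                      for r, grp in df.groupby("region")}
        return SelectionTable(designated, df.drop(columns=["designated"]))


@dataclass(frozen=True)
class AveragingEnsemble:
    members: tuple[str, str]
    sum_threshold: float = 1.0

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError("ensemble members must be distinct")


def average_predict(p_r: float, p_d: float) -> tuple[float, int]:
    """((p_r + p_d)/2, label) with label = 1 iff p_r + p_d >= 1."""
    for p in (p_r, p_d):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    return (p_r + p_d) / 2.0, int(p_r + p_d >= 1.0)


def _as_metric_frame(validation_metrics) -> pd.DataFrame:
    """Accept a DataFrame (model_id, region, auc, accuracy, kappa) or a
    mapping {(model_id, region): {metric: value}}."""
    if isinstance(validation_metrics, pd.DataFrame):
        df = validation_metrics.copy()
    else:
        rows = []
        for (mid, region), metrics in validation_metrics.items():
            rows.append({"model_id": mid, "region": region, **metrics})
        df = pd.DataFrame(rows)
    for c in ("model_id", "region"):
        if c not in df.columns:
            raise ValueError(f"validation metrics missing column {c!r}")
    return df


def designate_learners(validation_metrics, candidate_order=None) -> SelectionTable:
    """Per region, pick the model strictly best in >= 2 of the 3 metrics.

    Ties within a metric (within 1e-9) award no win.  If no model reaches
    two wins, the tie-break is highest AUC, then first in candidate order.
    Raises when any (model, region, metric) entry is missing.
    """
    df = _as_metric_frame(validation_metrics)
    models = candidate_order or sorted(df["model_id"].unique())
    if len(models) < 2:
        raise ValueError("designation needs at least 2 candidate models")
    regions = sorted(df["region"].unique())
    designated: dict[str, str] = {}
    prov_rows = []
    for region in regions:
        triplets = {}
        for mid in models:
            row = df[(df["model_id"] == mid) & (df["region"] == region)]
            if len(row) != 1:
                raise ValueError(f"missing metrics for ({mid!r}, {region!r})")
            for metric in DESIGNATION_METRICS:
                if metric not in row.columns or pd.isna(row[metric].iloc[0]):
                    raise ValueError(
                        f"missing metric {metric!r} for ({mid!r}, {region!r})")
            triplets[mid] = {m: float(row[m].iloc[0]) for m in DESIGNATION_METRICS}
            prov_rows.append({"region": region, "model_id": mid, **triplets[mid]})
        wins = {mid: 0 for mid in models}
        for metric in DESIGNATION_METRICS:
            vals = {mid: triplets[mid][metric] for mid in models}
            best = max(vals.values())
            leaders = [m for m in models if vals[m] >= best - WIN_TOLERANCE]
            if len(leaders) == 1:
                wins[leaders[0]] += 1
        two_plus = [m for m in models if wins[m] >= 2]
        if two_plus:
            designated[region] = two_plus[0]
        else:
            aucs = {mid: triplets[mid]["auc"] for mid in models}
            best_auc = max(aucs.values())
            leaders = [m for m in models if aucs[m] >= best_auc - WIN_TOLERANCE]
            designated[region] = leaders[0]  # fixed candidate order breaks ties
            log.info("region %s: no 2-of-3 winner; fell back to AUC/candidate order",
                     region)
    return SelectionTable(designated, pd.DataFrame(prov_rows))


def calibrated_predict(study: Study, selection: SelectionTable, region_models,
                       image_size: int | None = None,
                       provenance: dict | None = None) -> tuple[float, int]:
    """Route a study's views to its region's designated model.

    ``region_models`` maps region -> model exposing ``forward`` (a
    TrainableModel or TrainedModel).  Returns (study probability, label).
    """
    from .data_io import load_image, preprocess_image

    model_id = selection.model_for(study.region)
    if study.region not in region_models:
        raise KeyError(f"no model provided for region {study.region!r}")
    model = region_models[study.region]
    fwd = model.predict if hasattr(model, "predict") else model.forward
    if image_size is None:
        spec = getattr(model, "spec", None) or model.model.spec
        image_size = spec.input_shape[0]
    imgs = np.stack([preprocess_image(load_image(v.path), size=image_size)
                     for v in study.views])
    prob = study_probability(list(fwd(imgs)))
    if provenance is not None:
        provenance[study.study_id] = model_id
    return prob, classify_study(prob)


def route_table(table: PredictionTable, selection: SelectionTable,
                model_id: str = "calibrated") -> PredictionTable:
    """Build the calibrated model's prediction rows from per-model rows.

    Each study keeps the probability of its region's designated model;
    useful for evaluating the routed ensemble without re-running inference.
    """
    parts = []
    for region, grp in table.df.groupby("region"):
        winner = selection.model_for(region)
        sub = grp[grp["model_id"] == winner].copy()
        if len(sub) == 0:
            raise ValueError(f"no rows for designated model {winner!r} in {region!r}")
        sub["model_id"] = model_id
        parts.append(sub)
    return PredictionTable(pd.concat(parts, ignore_index=True))
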