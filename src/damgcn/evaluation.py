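"""Metric suite, transfer tasks, ablation grids and embedding export.

Metrics follow the conventions for imbalanced binary risk classification:
macro-averaged precision/recall/F1 (both classes weighted equally), the
Matthews correlation coefficient, balanced accuracy (mean per-class
recall) and ROC AUC computed from the positive-class probability. All of
them are delegated to scikit-learn; AUC is reported as missing (NaN) when
the evaluated split contains a single class.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .data_io import LabeledGraph, save_labels
from .model import ModelConfig
from .training import TrainConfig, TrainedModel, train_damgcn
from .walk_pmi import WalkConfig

logger = logging.getLogger("damgcn")

__all__ = [
    "MetricsReport",
    "compute_metrics",
    "evaluate_split",
    "run_transfer_task",
    "run_ablation_grid",
    "export_embeddings",
    "save_reports",
]

METRIC_COLUMNS = ["Accuracy", "AUC", "Precision", "Recall", "F1score",
                  "MCC", "Balanced accuracy"]


@dataclass
class MetricsReport:
    accuracy: float
    auc: float  # NaN when undefined (single-class truth)
    precision_macro: float
    recall_macro: float
    f1_macro: float
    mcc: float
    balanced_accuracy: float
    confusion: np.ndarray
    task_name: str = ""

    def as_row(self) -> list[float]:
        return [self.accuracy, self.auc, self.precision_macro,
                self.recall_macro, self.f1_macro, self.mcc,
                self.balanced_accuracy]

    def to_dict(self) -> dict:
        row = dict(zip(METRIC_COLUMNS, self.as_row()))
        return {"task": self.task_name,
                **{k: (None if np.isnan(v) else float(v)) for k, v in row.items()},
                "confusion": self.confusion.tolist()}


def compute_metrics(true_labels: np.ndarray, pred_labels: np.ndarray,
                    pos_probs: np.ndarray | None = None,
                    task_name: str = "") -> MetricsReport:
    """All seven evaluation statistics for one task.

    ``pos_probs`` (positive-class probability, binary tasks) is only needed
    for AUC; without it, or with single-class truth, AUC is NaN.
    """
    y, yhat = np.asarray(true_labels), np.asarray(pred_labels)
    if y.shape != yhat.shape:
        raise ValueError("true and predicted labels disagree in length")
    labels = np.arange(max(y.max(), yhat.max()) + 1)
    auc = float("nan")
    if pos_probs is not None:
        if np.unique(y).size < 2:
            logger.warning("AUC undefined: evaluation split has a single class")
        else:
            auc = float(roc_auc_score(y, np.asarray(pos_probs)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division on degenerate splits
        return MetricsReport(
            accuracy=float(accuracy_score(y, yhat)),
            auc=auc,
            precision_macro=float(precision_score(y, yhat, labels=labels,
                                                  average="macro", zero_division=0)),
            recall_macro=float(recall_score(y, yhat, labels=labels,
                                            average="macro", zero_division=0)),
            f1_macro=float(f1_score(y, yhat, labels=labels,
                                    average="macro", zero_division=0)),
            mcc=float(matthews_corrcoef(y, yhat)),
            balanced_accuracy=float(balanced_accuracy_score(y, yhat)),
            confusion=confusion_matrix(y, yhat, labels=labels),
            task_name=task_name,
        )


def evaluate_split(trained: TrainedModel, tag: str, split: str = "test",
                   task_name: str = "") -> MetricsReport:
    """Metrics of the fitted model's ``tag`` head on that domain's split."""
    graph = trained.source if tag == "source" else trained.target
    train_idx, test_idx = trained.splits[tag]
    idx = train_idx if split == "train" else test_idx
    probs = trained.predict_proba(tag)[idx]
    y = graph.labels[idx]
    pos = probs[:, 1] if probs.shape[1] == 2 else None
    return compute_metrics(y, probs.argmax(axis=1), pos, task_name=task_name)


def run_transfer_task(source_name: str, target_name: str,
                      datasets: dict[str, LabeledGraph],
                      model_cfg: ModelConfig | None = None,
                      train_cfg: TrainConfig | None = None,
                      walk_cfg: WalkConfig | None = None,
                      ) -> tuple[MetricsReport, MetricsReport, TrainedModel]:
    """Train source -> target and evaluate both domains' test splits.

    Returns (target report, source report, trained model); the task name is
    e.g. ``"H->D"``. Adaptation also tends to help the source domain, so
    its test metrics are reported alongside.
    """
    for name in (source_name, target_name):
        if name not in datasets:
            raise KeyError(f"unknown dataset {name!r}; "
                           f"available: {sorted(datasets)}")
    src = _with_tag(datasets[source_name], "source")
    tgt = _with_tag(datasets[target_name], "target")
    trained = train_damgcn(src, tgt, model_cfg, train_cfg, walk_cfg)
    task = f"{source_name}->{target_name}"
    rep_t = evaluate_split(trained, "target", "test", task_name=task)
    rep_s = evaluate_split(trained, "source", "test", task_name=f"{task} (source)")
    return rep_t, rep_s, trained


def run_ablation_grid(source: LabeledGraph, target: LabeledGraph,
                      model_cfg: ModelConfig | None = None,
                      train_cfg: TrainConfig | None = None,
                      walk_cfg: WalkConfig | None = None,
                      task_name: str = "") -> dict[str, MetricsReport]:
    """Target-test metrics for the full model and its three ablations."""
    train_cfg = train_cfg or TrainConfig()
    out: dict[str, MetricsReport] = {}
    for variant in ("full", "no_target", "no_global", "no_domain"):
        cfg = TrainConfig(**{**train_cfg.__dict__, "variant": variant})
        trained = train_damgcn(_with_tag(source, "source"),
                               _with_tag(target, "target"),
                               model_cfg, cfg, walk_cfg)
        out[variant] = evaluate_split(trained, "target", "test",
                                      task_name=f"{task_name}[{variant}]")
    return out


def export_embeddings(trained: TrainedModel | None, graph: LabeledGraph,
                      layer: str, matrix_path: str | Path,
                      labels_path: str | Path) -> np.ndarray:
    """Write node embeddings plus aligned labels for external 2-D projection.

    ``layer="raw"`` exports the original features; ``layer="fused"`` the
    final attention-fused embedding and requires a trained model.
    """
    if layer == "raw":
        mat = graph.features.values
    elif layer == "fused":
        if trained is None:
            raise ValueError("layer='fused' requires a trained model")
        mat = trained.embed(graph.domain_tag)
    else:
        raise ValueError("layer must be 'raw' or 'fused'")
    np.savetxt(matrix_path, mat, delimiter="\t", fmt="%.10g")
    save_labels(graph.labels, labels_path)
    return mat


def save_reports(reports: list[MetricsReport], tsv_path: str | Path,
                 json_path: str | Path | None = None) -> None:
    """One record per task: delimited text plus machine-readable JSON."""
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(["Task"] + METRIC_COLUMNS) + "\n")
        for rep in reports:
            fh.write("\t".join([rep.task_name] +
                               [f"{v:.6f}" for v in rep.as_row()]) + "\n")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump([rep.to_dict() for rep in reports], fh, indent=2)


def _with_tag(graph: LabeledGraph, tag: str) -> LabeledGraph:
    if graph.domain_tag == tag:
        return graph
    return LabeledGraph(adjacency=graph.adjacency, features=graph.features,
                        labels=graph.labels, domain_tag=tag)
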