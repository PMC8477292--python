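"""Task metrics (AUROC, F1, precision, recall) and the experiment grid.

AUROC is the Mann-Whitney probability that a uniformly random positive
outscores a uniformly random negative, ties counted 1/2 — computed via
average ranks.  Degenerate inputs (a single class) raise
:class:`UndefinedMetricError` and are reported as NA, never as 0.

The CA tasks are evaluated by masking the same trained model's scores to
cardiac-arrest records: one model, two masks per main target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "UndefinedMetricError",
    "TaskMetrics",
    "compute_auroc",
    "classification_metrics",
    "evaluate_model",
    "run_grid",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. single-class labels)."""


def compute_auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUROC with average-rank tie handling."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-d sequences")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUROC undefined: {n_pos} positives, {n_neg} negatives"
        )
    ranks = rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def classification_metrics(scores: Sequence[float], labels: Sequence[int],
                           threshold: float = 0.5) -> tuple[float, float, float]:
    """(precision, recall, f1) at a probability threshold.

    Conventions for degenerate confusion matrices: precision = 0 with no
    predicted positives, recall = 0 with no true positives, f1 = 0 when
    precision + recall = 0.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1) on the probability scale")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    pred = s >= threshold
    tp = float(np.sum(pred & (y == 1)))
    fp = float(np.sum(pred & (y == 0)))
    fn = float(np.sum(~pred & (y == 1)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


def best_f1_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold (from the observed score set) maximizing F1; for use on the
    validation split when the fixed 0.5 convention is not wanted."""
    s = np.asarray(scores, dtype=float)
    best_t, best_f1 = 0.5, -1.0
    for t in np.unique(np.clip(s, 1e-6, 1 - 1e-6)):
        _, _, f1 = classification_metrics(s, labels, float(t))
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t


@dataclass
class TaskMetrics:
    task: str
    auroc: float
    f1: float
    precision: float
    recall: float
    n_records: int
    n_positive: int


def _metrics_for(task: str, scores: np.ndarray, labels: np.ndarray,
                 threshold: float) -> TaskMetrics:
    n = int(labels.size)
    n_pos = int(labels.sum())
    if n == 0 or n_pos == 0 or n_pos == n:
        return TaskMetrics(task, float("nan"), float("nan"), float("nan"),
                           float("nan"), n, n_pos)
    auroc = compute_auroc(scores, labels)
    precision, recall, f1 = classification_metrics(scores, labels, threshold)
    return TaskMetrics(task, auroc, f1, precision, recall, n, n_pos)


def evaluate_model(trained, split: str = "test", threshold: float = 0.5
                   ) -> list[TaskMetrics]:
    """ALL-task and CA-subset metrics for the model's main target on a split.

    ``trained`` is a :class:`hvec.training.TrainedModel`; ``split`` is one of
    train/val/test.  CA metrics use only cardiac-arrest records; an empty or
    single-class CA subset yields NA metrics with its record count.
    """
    persons_by_id = {p.person_id: p for p in trained._run_data.cohort.persons}
    persons = [persons_by_id[pid] for pid in trained.split_ids[split]]
    task = trained.config.main_task
    _, scores, labels, is_ca = trained.predict_scores(persons, task)
    ca = is_ca > 0.5
    return [
        _metrics_for(f"ALL-{task}", scores, labels, threshold),
        _metrics_for(f"CA-{task}", scores[ca], labels[ca], threshold),
    ]


def run_grid(cohort, grid: Sequence, seeds: Sequence[int],
             params=None, out_path: Optional[str] = None) -> pd.DataFrame:
    """Train and evaluate every (config, seed) cell; one row per task.

    ``grid`` is a sequence of :class:`hvec.training.TrainingConfig`;
    each run's config gets the cell's seed.  Failures are recorded in an
    ``error`` column and skipped, not fatal.  Returns a tidy table
    (config fields, seed, task, auroc, f1, precision, recall) and writes it
    as CSV when ``out_path`` is given.
    """
    from dataclasses import replace

    from .featurization import featurize_cohort_raw, make_table_for_cohort
    from .model import HVecParams
    from .training import train

    if not grid:
        raise ValueError("grid must be non-empty")
    params = params or HVecParams()
    table = make_table_for_cohort(cohort, dimension=params.code_embed_size,
                                  seed=params.init_seed)
    raw = featurize_cohort_raw(cohort, table)

    rows = []
    for config in grid:
        for seed in seeds:
            cfg = replace(config, seed=int(seed))
            base = {
                "main_task": cfg.main_task,
                "multitask": cfg.multitask,
                "upsampling_rate": cfg.upsampling_rate,
                "event_weight": cfg.event_weight_pos,
                "seed": int(seed),
            }
            try:
                trained, _ = train(cohort, params=params, config=cfg,
                                   raw_features=raw, table=table)
                for tm in evaluate_model(trained, "test"):
                    rows.append({**base, "task": tm.task, "auroc": tm.auroc,
                                 "f1": tm.f1, "precision": tm.precision,
                                 "recall": tm.recall, "n_records": tm.n_records,
                                 "n_positive": tm.n_positive, "error": ""})
            except Exception as exc:  # record and continue
                rows.append({**base, "task": "", "auroc": float("nan"),
                             "f1": float("nan"), "precision": float("nan"),
                             "recall": float("nan"), "n_records": 0,
                             "n_positive": 0, "error": f"{type(exc).__name__}: {exc}"})
    table_df = pd.DataFrame(rows)
    if out_path:
        table_df.to_csv(out_path, index=False)
    return table_df


def summarize_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd over seeds per (config, task): the layout of the
    upsampling-rate x event-weight experiment tables."""
    ok = results[results["error"] == ""]
    return (ok.groupby(["main_task", "multitask", "upsampling_rate",
                        "event_weight", "task"])
              .agg(auroc_mean=("auroc", "mean"), auroc_sd=("auroc", "std"),
                   f1_mean=("f1", "mean"), f1_sd=("f1", "std"),
                   n_seeds=("seed", "nunique"))
              .reset_index())
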