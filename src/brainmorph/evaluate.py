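"""Leave-one-out linear-SVM evaluation with monotone score calibration.

The evaluation contract: for each subject, fit an optional z-score
normalizer and a linear SVM (C = 1 by default) on all remaining subjects,
record the held-out signed decision value, then

* threshold raw decision values at 0 (the SVM margin sign) for the
  confusion matrix and ACC / SEN / SPE / F1S,
* map raw scores through a strictly increasing (injective monotone)
  calibration onto [0, 1] — affine min-max by default — which by
  construction changes neither the confusion matrix nor the ROC/AUC,
* sweep all distinct score thresholds for the ROC curve and compute AUC by
  the trapezoidal rule (equal to the Mann-Whitney pair-ordering statistic,
  ties at half credit).

The positive class is the clinical class (CI or T2DM), fixing the
directionality of sensitivity and specificity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

TASKS = {
    # task name -> (column, positive value)
    "CI_vs_NC": ("cognition", "CI"),
    "T2DM_vs_NT": ("diagnosis", "T2DM"),
}

SUBGROUPS: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "ci_only": lambda df: df["cognition"] == "CI",
    "nc_only": lambda df: df["cognition"] == "NC",
    "t2dm_only": lambda df: df["diagnosis"] == "T2DM",
    "nt_only": lambda df: df["diagnosis"] == "NT",
}

#: per-method default feature normalization inside the LOOCV loop
METHOD_NORMALIZE = {"VOR": "none", "PBM": "none", "LEP": "zscore", "DTL": "zscore"}


class EvalError(ValueError):
    """Raised for invalid evaluation inputs (missing classes, bad folds)."""


@dataclass
class SvmConfig:
    """Linear SVM + normalization settings for the LOOCV harness."""

    C: float = 1.0
    kernel: str = "linear"
    normalize: str = "none"  # "none" | "zscore", fitted on the training fold

    def validate(self) -> "SvmConfig":
        if self.C <= 0:
            raise EvalError(f"C must be > 0, got {self.C}")
        if self.kernel != "linear":
            raise EvalError("only the linear kernel is supported")
        if self.normalize not in ("none", "zscore"):
            raise EvalError(f"normalize must be 'none' or 'zscore', got {self.normalize!r}")
        return self


@dataclass
class TaskLabels:
    """Binary labels for one task, aligned with feature-matrix rows."""

    subject_ids: list[str]
    y: np.ndarray
    task: str
    subgroup_filter: str | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.subject_ids) != len(self.y):
            raise EvalError("subject_ids and y lengths differ")
        classes = set(np.unique(self.y).tolist())
        if not classes <= {0, 1}:
            raise EvalError(f"labels must be binary 0/1, got {sorted(classes)}")
        if classes != {0, 1}:
            raise EvalError("both classes must be present")


@dataclass
class EvalReport:
    """Confusion counts, the four scalar metrics, ROC points and AUC."""

    task: str
    method: str
    subgroup: str | None
    subject_ids: list[str]
    y_true: np.ndarray
    scores: np.ndarray  # raw signed decision values
    calibrated: np.ndarray  # strictly-increasing map of scores onto [0, 1]
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sen: float
    spe: float
    f1s: float
    roc: list[tuple[float, float]]  # (FPR, TPR) points
    auc: float
    config: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def metrics(self) -> dict:
        return {
            "acc": self.acc,
            "sen": self.sen,
            "spe": self.spe,
            "f1s": self.f1s,
            "auc": self.auc,
        }

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "method": self.method,
            "subgroup": self.subgroup,
            "n": self.n,
            "n_positive": int(self.y_true.sum()),
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "metrics": self.metrics(),
            "roc": [[float(f), float(t)] for f, t in self.roc],
            "per_subject": {
                "subject_ids": list(self.subject_ids),
                "y_true": self.y_true.astype(int).tolist(),
                "scores": [float(s) for s in self.scores],
                "calibrated": [float(s) for s in self.calibrated],
            },
            "config": self.config,
        }


def make_labels(
    table: pd.DataFrame, task: str, subgroup: str | None = None
) -> tuple[TaskLabels, pd.DataFrame]:
    """Build binary labels for a task, optionally on a subgroup.

    Returns the labels and the (possibly filtered) subject table, row-aligned.
    """
    if task not in TASKS:
        raise EvalError(f"unknown task {task!r}; choose from {sorted(TASKS)}")
    df = table
    if subgroup is not None:
        if subgroup not in SUBGROUPS:
            raise EvalError(
                f"unknown subgroup {subgroup!r}; choose from {sorted(SUBGROUPS)}"
            )
        df = df[SUBGROUPS[subgroup](df)].reset_index(drop=True)
        if df.empty:
            raise EvalError(f"subgroup {subgroup!r} selects no subjects")
    column, positive = TASKS[task]
    y = (df[column] == positive).to_numpy(dtype=int)
    labels = TaskLabels(
        subject_ids=[str(s) for s in df["subject_id"]],
        y=y,
        task=task,
        subgroup_filter=subgroup,
    )
    return labels, df


def _make_pipeline(cfg: SvmConfig) -> Pipeline:
    steps = []
    if cfg.normalize == "zscore":
        steps.append(("zscore", StandardScaler()))
    steps.append(("svm", SVC(kernel="linear", C=cfg.C)))
    return Pipeline(steps)


def loocv_predict(
    X: np.ndarray, y: np.ndarray, cfg: SvmConfig | None = None
) -> np.ndarray:
    """Held-out signed decision values from leave-one-out refits.

    For each subject i the normalizer (if any) and the SVM are fitted on all
    other subjects and the signed decision value for subject i is recorded.
    Deterministic given the inputs.
    """
    cfg = (cfg or SvmConfig()).validate()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 3:
        raise EvalError(f"need at least 3 subjects for LOOCV, got {n}")
    if set(np.unique(y).tolist()) != {0, 1}:
        raise EvalError("both classes must be present")
    template = _make_pipeline(cfg)
    scores = np.empty(n, dtype=np.float64)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        y_train = y[train]
        if len(np.unique(y_train)) < 2:
            raise EvalError(
                f"training fold {i} (holding out {i}) contains a single class"
            )
        model = clone(template)
        model.fit(X[train], y_train)
        scores[i] = float(model.decision_function(X[i : i + 1])[0])
    return scores


def calibrate_scores(scores: np.ndarray) -> np.ndarray:
    """Affine min-max calibration of raw scores onto [0, 1].

    The map is strictly increasing (injective monotone), so score ranks —
    and therefore ROC, AUC and any threshold-matched confusion matrix — are
    unchanged.  Raises if all scores are identical (no injective map exists).
    """
    scores = np.asarray(scores, dtype=np.float64)
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        raise EvalError("cannot calibrate: all scores are identical")
    return (scores - lo) / (hi - lo)


def compute_metrics(
    scores: np.ndarray,
    y: np.ndarray,
    threshold: float = 0.0,
    task: str = "",
    method: str = "",
    subgroup: str | None = None,
    subject_ids: Sequence[str] | None = None,
    config: dict | None = None,
) -> EvalReport:
    """Confusion counts at ``threshold`` plus ROC curve and AUC.

    Predictions are positive when ``score >= threshold``.  The ROC curve
    sweeps all distinct score thresholds (plus the endpoints) and AUC is the
    trapezoidal area, identical to the Mann-Whitney statistic with ties at
    half credit.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if scores.shape != y.shape:
        raise EvalError(f"scores shape {scores.shape} != labels shape {y.shape}")
    if set(np.unique(y).tolist()) != {0, 1}:
        raise EvalError("both classes must be present to compute metrics")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = len(y)
    acc = (tp + tn) / n
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    f1s = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    auc = float(roc_auc_score(y, scores))
    if subject_ids is None:
        subject_ids = [str(i) for i in range(n)]
    try:
        calibrated = calibrate_scores(scores)
    except EvalError:
        calibrated = np.full(n, 0.5)  # degenerate constant scores
    return EvalReport(
        task=task,
        method=method,
        subgroup=subgroup,
        subject_ids=list(subject_ids),
        y_true=y,
        scores=scores,
        calibrated=calibrated,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        acc=acc,
        sen=sen,
        spe=spe,
        f1s=f1s,
        roc=[(float(f), float(t)) for f, t in zip(fpr, tpr)],
        auc=auc,
        config=dict(config or {}),
    )


def run_task(
    features: FeatureMatrix,
    table: pd.DataFrame,
    task: str,
    subgroup: str | None = None,
    cfg: SvmConfig | None = None,
) -> EvalReport:
    """Label construction + LOOCV + calibration + metrics for one task.

    Feature rows are aligned to the subject table by subject id; the
    normalization default follows the feature method (z-score for LEP/DTL,
    none for VOR/PBM) unless overridden in ``cfg``.
    """
    if cfg is None:
        cfg = SvmConfig(normalize=METHOD_NORMALIZE.get(features.method, "none"))
    cfg.validate()
    labels, df = make_labels(table, task, subgroup)
    row_of = {sid: i for i, sid in enumerate(features.subject_ids)}
    missing = [sid for sid in labels.subject_ids if sid not in row_of]
    if missing:
        raise EvalError(f"subjects missing from feature matrix: {missing[:5]}")
    X = features.values[[row_of[sid] for sid in labels.subject_ids]]
    if labels.y.sum() < 2 or (len(labels.y) - labels.y.sum()) < 2:
        raise EvalError(
            f"task {task} (subgroup={subgroup}) needs >= 2 subjects per class"
        )
    scores = loocv_predict(X, labels.y, cfg)
    report = compute_metrics(
        scores,
        labels.y,
        threshold=0.0,
        task=task,
        method=features.method,
        subgroup=subgroup,
        subject_ids=labels.subject_ids,
        config=dataclasses.asdict(cfg),
    )
    return report
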