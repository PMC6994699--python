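"""Subject-level case-vs-control classification with support vector
machines, leave-one-subject-out cross-validation and ROC/AUC.

Each subject is scored by a linear-kernel SVM (C = 1) that never saw it:
feature standardization and model fitting happen inside each training
fold, and the held-out decision scores are pooled into a single ROC
curve.  The trapezoidal AUC equals the Mann-Whitney rank statistic
U / (n_pos * n_neg) exactly; both are computed and cross-checked.

Two feature sets are compared: baseline morphofunctional features alone,
and baseline + FCCP-challenge features concatenated per subject.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc, roc_curve
from sklearn.model_selection import LeaveOneOut
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .morphometrics import CELL_FEATURES, MITO_FEATURES

__all__ = ["ClassificationReport", "build_feature_matrix",
           "cross_validated_svm", "compare_modes", "roc_auc"]

DEFAULT_FEATURES = MITO_FEATURES + CELL_FEATURES


@dataclass
class ClassificationReport:
    """Cross-validated classification outcome for one feature mode."""

    mode: str
    subjects: list[str]
    labels: np.ndarray  # 1 = case, 0 = control
    scores: np.ndarray  # pooled held-out decision scores
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    scheme: str = "leave-one-subject-out"
    seed: int = 0

    def roc_points(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def build_feature_matrix(subjects: pd.DataFrame, mode: str = "baseline",
                         features: list[str] | None = None,
                         group_col: str = "group",
                         case_label: str = "case"):
    """Assemble the subject x feature matrix for one classification mode.

    ``subjects`` is a per-subject-x-condition table (one row per subject
    and condition).  ``mode="baseline"`` uses the baseline rows only;
    ``mode="baseline+FCCP"`` concatenates the baseline and FCCP feature
    blocks per subject (column names suffixed by condition).  Subjects
    missing a required condition are dropped (logged).  No
    standardization happens here -- scaling is fitted inside training
    folds during cross-validation.

    Returns ``(X DataFrame, y ndarray, subject ids)``.
    """
    if mode not in ("baseline", "baseline+FCCP"):
        raise ValueError(f"unknown mode {mode!r}")
    features = list(features or DEFAULT_FEATURES)
    features = [f for f in features if f in subjects.columns]
    conditions = ["baseline"] if mode == "baseline" else ["baseline", "FCCP"]
    blocks = []
    for cond in conditions:
        sub = subjects[subjects["condition"] == cond]
        block = sub.set_index("subject_id")[features]
        block.columns = [f"{c}_{cond}" for c in features]
        blocks.append(block)
    X = pd.concat(blocks, axis=1, join="inner").sort_index()
    dropped = set(subjects["subject_id"]) - set(X.index)
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "dropped subjects missing a condition: %s", sorted(dropped))
    groups = (subjects.drop_duplicates("subject_id")
              .set_index("subject_id")[group_col])
    y = (groups.loc[X.index] == case_label).to_numpy(dtype=int)
    return X, y, list(X.index)


def roc_auc(labels: np.ndarray, scores: np.ndarray):
    """ROC curve and trapezoidal AUC from pooled decision scores."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def mann_whitney_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the rank-statistic identity U / (n_pos * n_neg)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    u = (np.sum(pos[:, None] > neg[None, :])
         + 0.5 * np.sum(pos[:, None] == neg[None, :]))
    return float(u / (len(pos) * len(neg)))


def cross_validated_svm(X, y, subjects=None, C: float = 1.0,
                        kernel: str = "linear",
                        seed: int = 0) -> ClassificationReport:
    """Leave-one-subject-out SVM classification with pooled-score ROC.

    Standardization (z-score) is fitted on the training fold only; the
    held-out subject's decision score comes from a model that never saw
    it.  Class weights are balanced: leaving one subject out always
    unbalances the training classes, which otherwise biases pooled
    held-out scores (and the null AUC) downward.  Deterministic for
    fixed inputs and seed.
    """
    X = np.asarray(X, dtype=np.float64) if not isinstance(X, pd.DataFrame) \
        else X.to_numpy(dtype=np.float64)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("single-class input")
    if counts.min() < 3:
        raise ValueError("need at least 3 subjects per class")
    scores = np.empty(len(y), dtype=np.float64)
    for train, test in LeaveOneOut().split(X):
        model = make_pipeline(
            StandardScaler(),
            SVC(kernel=kernel, C=C, class_weight="balanced",
                random_state=seed))
        model.fit(X[train], y[train])
        scores[test] = model.decision_function(X[test])
    fpr, tpr, auc_val = roc_auc(y, scores)
    return ClassificationReport(
        mode="", subjects=list(subjects) if subjects is not None
        else [str(i) for i in range(len(y))],
        labels=y, scores=scores, fpr=fpr, tpr=tpr, auc=auc_val, seed=seed)


def classify_subjects(subject_table: pd.DataFrame, mode: str = "baseline",
                      features: list[str] | None = None, C: float = 1.0,
                      seed: int = 0) -> ClassificationReport:
    """Build the feature matrix for ``mode`` and run leave-one-out SVM."""
    X, y, sids = build_feature_matrix(subject_table, mode=mode,
                                      features=features)
    report = cross_validated_svm(X, y, subjects=sids, C=C, seed=seed)
    report.mode = mode
    return report


def compare_modes(report_baseline: ClassificationReport,
                  report_combined: ClassificationReport) -> dict:
    """Summarize the AUC gain from adding FCCP-challenge features."""
    if report_baseline.subjects != report_combined.subjects:
        raise ValueError("reports cover different subject sets")
    return {
        "auc_baseline": report_baseline.auc,
        "auc_combined": report_combined.auc,
        "delta_auc": report_combined.auc - report_baseline.auc,
        "n_subjects": len(report_baseline.subjects),
    }
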