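"""Subject classification from snapshot clustering-coefficient series.

Each snapshot of a subject's extended dynamic network (interpolated
in-snapshots followed by extrapolated out-snapshots) contributes one global
clustering coefficient; the concatenated series is the subject's feature
vector.  Diagnostic groups are separated pairwise (disease vs control) with
stratified cross-validated classifiers (SVM with RBF kernel by default; KNN
and Gaussian naive Bayes for comparison).  Features are standardized inside
each training fold only, so no information leaks from test folds.
Sensitivity is the recall on the disease group, specificity the recall on
the control group, and AUC is computed from pooled decision scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .graph_metrics import binarize, global_clustering
from .snapshots import SnapshotSequence

logger = logging.getLogger("dynbrain")

__all__ = [
    "FeatureTable",
    "FoldMetrics",
    "ClassificationReport",
    "extract_features",
    "classify",
    "ablation",
]


@dataclass
class FeatureTable:
    """Per-subject clustering-coefficient series with group labels."""

    rows: list[tuple[str, str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(r[2]) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"feature vectors of unequal length: {sorted(lengths)}")
        for _, _, v in self.rows:
            v = np.asarray(v, dtype=float)
            if np.any((v < -1e-9) | (v > 1 + 1e-9)):
                raise ValueError("clustering coefficients must lie in [0, 1]")

    def add(self, subject_id: str, group_label: str, features: np.ndarray) -> None:
        self.rows.append((subject_id, group_label, np.asarray(features, dtype=float)))
        self.__post_init__()

    def subset(self, groups: tuple[str, str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
        X, y, ids = [], [], []
        for sid, grp, v in self.rows:
            if grp in groups:
                X.append(v)
                y.append(grp)
                ids.append(sid)
        return np.asarray(X), np.asarray(y), ids

    def to_frame(self) -> pd.DataFrame:
        k = len(self.rows[0][2]) if self.rows else 0
        data = {
            "subject_id": [r[0] for r in self.rows],
            "group": [r[1] for r in self.rows],
        }
        for j in range(k):
            data[f"f_{j + 1}"] = [r[2][j] for r in self.rows]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        feat_cols = [c for c in df.columns if c.startswith("f_")]
        rows = [
            (str(r["subject_id"]), str(r["group"]),
             np.asarray([r[c] for c in feat_cols], dtype=float))
            for _, r in df.iterrows()
        ]
        return cls(rows=rows)


@dataclass
class FoldMetrics:
    fold: int
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def accuracy(self) -> float:
        n = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / n if n else float("nan")


@dataclass
class ClassificationReport:
    """Cross-validated binary classification metrics (percent scale), with
    per-fold confusion counts; aggregates are computed from pooled counts."""

    classifier_name: str
    group_a: str   # disease (positive)
    group_b: str   # control (negative)
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    fold_details: list[FoldMetrics]
    config: dict

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier_name,
            "contrast": f"{self.group_a} vs {self.group_b}",
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "auc": self.auc,
            "folds": [vars(f) for f in self.fold_details],
            "config": self.config,
        }


def extract_features(
    in_snaps: SnapshotSequence,
    out_snaps: SnapshotSequence | None = None,
    density: float = 0.15,
) -> np.ndarray:
    """Global clustering coefficient of each snapshot, in-snapshots first."""
    snaps = list(in_snaps) + (list(out_snaps) if out_snaps is not None else [])
    if not snaps:
        raise ValueError("no snapshots to extract features from")
    return np.asarray(
        [global_clustering(binarize(s, density)) for s in snaps], dtype=float
    )


def _make_estimator(classifier: str, seed: int, svm_c: float = 1.0,
                    knn_k: int = 5):
    if classifier == "svm":
        clf = SVC(kernel="rbf", C=svm_c, random_state=seed)
    elif classifier == "knn":
        clf = KNeighborsClassifier(n_neighbors=knn_k)
    elif classifier == "nb":
        clf = GaussianNB()
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    return make_pipeline(StandardScaler(), clf)


def _scores(pipe, X) -> np.ndarray:
    last = pipe[-1]
    if hasattr(last, "decision_function"):
        return pipe.decision_function(X)
    return pipe.predict_proba(X)[:, 1]


def classify(
    table: FeatureTable,
    group_a: str,
    group_b: str,
    classifier: str = "svm",
    n_folds: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified cross-validated binary classification of group_a (disease)
    vs group_b (control)."""
    groups_present = {r[1] for r in table.rows}
    for g in (group_a, group_b):
        if g not in groups_present:
            raise ValueError(f"group {g!r} absent from feature table")
    X, y, _ = table.subset((group_a, group_b))
    n_a = int(np.sum(y == group_a))
    n_b = int(np.sum(y == group_b))
    if min(n_a, n_b) < n_folds:
        raise ValueError(
            f"n_folds={n_folds} exceeds smallest group size {min(n_a, n_b)}"
        )
    y_bin = (y == group_a).astype(int)   # disease positive
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    pooled_scores = np.zeros(len(y_bin))
    pooled_pred = np.zeros(len(y_bin), dtype=int)
    for f, (tr, te) in enumerate(skf.split(X, y_bin)):
        pipe = _make_estimator(classifier, seed)
        pipe.fit(X[tr], y_bin[tr])
        pred = pipe.predict(X[te])
        pooled_pred[te] = pred
        pooled_scores[te] = _scores(pipe, X[te])
        tp = int(np.sum((pred == 1) & (y_bin[te] == 1)))
        tn = int(np.sum((pred == 0) & (y_bin[te] == 0)))
        fp = int(np.sum((pred == 1) & (y_bin[te] == 0)))
        fn = int(np.sum((pred == 0) & (y_bin[te] == 1)))
        folds.append(FoldMetrics(fold=f, tp=tp, tn=tn, fp=fp, fn=fn))
    tp = sum(f.tp for f in folds)
    tn = sum(f.tn for f in folds)
    fp = sum(f.fp for f in folds)
    fn = sum(f.fn for f in folds)
    acc = 100.0 * (tp + tn) / len(y_bin)
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    auc = float(roc_auc_score(y_bin, pooled_scores))
    report = ClassificationReport(
        classifier_name=classifier,
        group_a=group_a,
        group_b=group_b,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        fold_details=folds,
        config={"n_folds": n_folds, "seed": seed, "kernel": "rbf",
                "n_neighbors": 5, "standardized": True},
    )
    logger.info(
        "%s vs %s (%s): acc %.1f%%, sens %.1f%%, spec %.1f%%, AUC %.2f",
        group_a, group_b, classifier, acc, sens, spec, auc,
    )
    return report


def ablation(
    table_in_only: FeatureTable,
    table_out_only: FeatureTable,
    table_both: FeatureTable,
    group_a: str,
    group_b: str,
    classifier: str = "svm",
    n_folds: int = 5,
    seed: int = 0,
) -> dict[str, ClassificationReport]:
    """Classify in-only, out-only and combined feature tables with identical
    folds and seed; side-by-side comparison of the snapshot contributions."""
    tables = {"in": table_in_only, "out": table_out_only, "both": table_both}
    subj_sets = {
        name: [(r[0], r[1]) for r in t.rows] for name, t in tables.items()
    }
    if len({tuple(s) for s in subj_sets.values()}) != 1:
        raise ValueError("tables must cover the same subjects in the same order")
    return {
        name: classify(t, group_a, group_b, classifier=classifier,
                       n_folds=n_folds, seed=seed)
        for name, t in tables.items()
    }
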