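"""Descriptor matrix assembly, learner scanning and classification metrics.

Descriptors are the contact-fingerprint bits plus the named scoring values;
each docked pose is one row carrying its compound's activity class, so pose
multiplicity acts as data augmentation.  Model quality is judged by accuracy
and Cohen's kappa under leave-20%-out (5-fold) cross-validation on the
training partition and by external testing on the held-out compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GroupKFold, KFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .io_model import ACTIVE, INACTIVE, INTERMEDIATE
from .labeling_split import SplitAssignment

DEFAULT_CV_FOLDS = 5  # leave-20%-out


# ---------------------------------------------------------------------------
# confusion counts, accuracy, kappa
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    """A k×k confusion table (rows = true class, columns = predicted)."""

    table: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        k = len(self.classes)
        if self.table.shape != (k, k):
            raise ValueError("confusion table must be square over `classes`")
        if (self.table < 0).any():
            raise ValueError("confusion counts must be non-negative")
        if self.N <= 0:
            raise ValueError("confusion table is empty (N = 0)")

    @classmethod
    def binary(cls, tp: int, tn: int, fp: int, fn: int) -> "ConfusionCounts":
        """2×2 table with the positive class first (TP in the top-left)."""
        return cls(table=np.array([[tp, fn], [fp, tn]], float), classes=["pos", "neg"])

    @classmethod
    def from_labels(
        cls,
        y_true: Sequence[str],
        y_pred: Sequence[str],
        classes: Sequence[str] | None = None,
    ) -> "ConfusionCounts":
        if len(y_true) != len(y_pred):
            raise ValueError("y_true and y_pred length mismatch")
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        index = {c: i for i, c in enumerate(classes)}
        table = np.zeros((len(classes), len(classes)))
        for t, p in zip(y_true, y_pred):
            table[index[t], index[p]] += 1
        return cls(table=table, classes=list(classes))

    @property
    def N(self) -> float:
        return float(self.table.sum())

    # binary accessors (positive class = classes[0])
    @property
    def TP(self) -> float:
        return float(self.table[0, 0])

    @property
    def TN(self) -> float:
        return float(self.table[1, 1])

    @property
    def FP(self) -> float:
        return float(self.table[1, 0])

    @property
    def FN(self) -> float:
        return float(self.table[0, 1])


def accuracy(counts: ConfusionCounts) -> float:
    """Observed agreement: trace / N ((TP + TN) / N in the binary case)."""
    return float(np.trace(counts.table) / counts.N)


def cohens_kappa(counts: ConfusionCounts) -> float:
    """Chance-corrected agreement ``(P0 - Pe) / (1 - Pe)``.

    ``Pe`` is the chance agreement from row×column marginal products.  In the
    degenerate case ``Pe = 1`` (all mass in one cell of a one-class table)
    kappa is returned as 0.0.
    """
    n = counts.N
    p0 = accuracy(counts)
    row = counts.table.sum(axis=1) / n
    col = counts.table.sum(axis=0) / n
    pe = float(np.dot(row, col))
    if abs(1.0 - pe) < 1e-12:
        return 0.0
    return float((p0 - pe) / (1.0 - pe))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float


def roc_curve(
    scores: Mapping[str, float],
    labels: Mapping[str, str],
    pos_label: str = "pos",
) -> RocResult:
    """Trapezoidal AUC plus the Youden-J-optimal operating point.

    ``scores`` and ``labels`` are keyed by item id; higher scores should
    indicate the positive class.  Raises if only one class is present.
    """
    from sklearn.metrics import auc as sk_auc
    from sklearn.metrics import roc_curve as sk_roc_curve

    items = sorted(scores)
    if set(items) != set(labels):
        raise ValueError("scores and labels must cover the same items")
    y = np.array([1 if labels[i] == pos_label else 0 for i in items])
    s = np.array([scores[i] for i in items], dtype=float)
    if y.min() == y.max():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = sk_roc_curve(y, s)
    area = float(sk_auc(fpr, tpr))
    j = tpr - fpr
    best = int(np.argmax(j))
    return RocResult(
        auc=area,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        threshold=float(thresholds[best]),
    )


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Rows = docked poses, columns = contact bits then scoring values."""

    X: np.ndarray
    columns: list[str]
    pose_ids: list[str]
    labels: dict[str, str]
    compound_of: dict[str, str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.pose_ids), len(self.columns)):
            raise ValueError("X shape inconsistent with pose_ids/columns")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate column names")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")
        missing = [p for p in self.pose_ids if p not in self.labels]
        if missing:
            raise ValueError(f"unlabelled poses: {missing[:5]}")

    def y(self) -> np.ndarray:
        return np.array([self.labels[p] for p in self.pose_ids])

    def groups(self) -> np.ndarray:
        return np.array([self.compound_of[p] for p in self.pose_ids])

    def subset_rows(self, keep: Sequence[bool] | np.ndarray) -> "FeatureMatrix":
        keep = np.asarray(keep, dtype=bool)
        pose_ids = [p for p, k in zip(self.pose_ids, keep) if k]
        return FeatureMatrix(
            X=self.X[keep],
            columns=list(self.columns),
            pose_ids=pose_ids,
            labels={p: self.labels[p] for p in pose_ids},
            compound_of={p: self.compound_of[p] for p in pose_ids},
        )

    def subset_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        index = {c: i for i, c in enumerate(self.columns)}
        cols = [index[n] for n in names]
        return FeatureMatrix(
            X=self.X[:, cols],
            columns=list(names),
            pose_ids=list(self.pose_ids),
            labels=dict(self.labels),
            compound_of=dict(self.compound_of),
        )

    def drop_class(self, activity_class: str = INTERMEDIATE) -> "FeatureMatrix":
        keep = np.array([self.labels[p] != activity_class for p in self.pose_ids])
        return self.subset_rows(keep)


def assemble_features(
    fp_matrix: np.ndarray,
    pose_ids: Sequence[str],
    axis_ids: Sequence[str],
    score_table,
    labels_by_compound: Mapping[str, str],
    compound_of: Mapping[str, str],
) -> FeatureMatrix:
    """Join contact bits with scoring values into one labelled matrix.

    Poses missing from the score table are dropped (they carry no scoring
    descriptors); labels are inherited from the pose's compound.
    """
    score_names = score_table.score_names
    keep_idx = [i for i, p in enumerate(pose_ids) if p in score_table.rows]
    kept_ids = [pose_ids[i] for i in keep_idx]
    scores = np.array(
        [[score_table.rows[p][n] for n in score_names] for p in kept_ids], float
    ).reshape(len(kept_ids), len(score_names))
    X = np.hstack([np.asarray(fp_matrix, float)[keep_idx], scores])
    labels = {p: labels_by_compound[compound_of[p]] for p in kept_ids}
    return FeatureMatrix(
        X=X,
        columns=list(axis_ids) + score_names,
        pose_ids=kept_ids,
        labels=labels,
        compound_of={p: compound_of[p] for p in kept_ids},
    )


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------


class PNNClassifier(BaseEstimator, ClassifierMixin):
    """Probabilistic neural network: Gaussian-kernel class-density classifier.

    ``p(c | x) ∝ prior(c) · mean_i exp(-||x - x_i^c||² / (2σ²))``.  With
    ``bandwidth=None`` σ is chosen from ``bandwidth_grid`` by internal 3-fold
    cross-validated accuracy.  Inputs are expected pre-scaled (the learner
    factory wraps the PNN in a standardising pipeline).
    """

    def __init__(
        self,
        bandwidth: float | None = None,
        bandwidth_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0),
        random_state: int = 0,
    ):
        self.bandwidth = bandwidth
        self.bandwidth_grid = bandwidth_grid
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.X_by_class_ = [X[y_idx == i] for i in range(len(self.classes_))]
        self.priors_ = np.array([len(g) for g in self.X_by_class_], float)
        self.priors_ /= self.priors_.sum()
        if self.bandwidth is not None:
            self.bandwidth_ = float(self.bandwidth)
        else:
            self.bandwidth_ = self._select_bandwidth(X, y)
        return self

    def _select_bandwidth(self, X, y) -> float:
        cv = KFold(n_splits=3, shuffle=True, random_state=self.random_state)
        best, best_acc = self.bandwidth_grid[0], -1.0
        for bw in self.bandwidth_grid:
            correct = 0
            for train_idx, test_idx in cv.split(X):
                if len(np.unique(y[train_idx])) < 2:
                    continue
                model = PNNClassifier(bandwidth=bw).fit(X[train_idx], y[train_idx])
                correct += int(np.sum(model.predict(X[test_idx]) == y[test_idx]))
            acc = correct / len(y)
            if acc > best_acc:
                best, best_acc = bw, acc
        return float(best)

    def _log_densities(self, X) -> np.ndarray:
        from scipy.special import logsumexp
        from scipy.spatial.distance import cdist

        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes_)))
        inv = 1.0 / (2.0 * self.bandwidth_**2)
        for i, pts in enumerate(self.X_by_class_):
            sq = cdist(X, pts, "sqeuclidean")
            out[:, i] = logsumexp(-sq * inv, axis=1) - np.log(len(pts))
        return out

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        logp = self._log_densities(X) + np.log(self.priors_)
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _scaled(estimator) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("model", estimator)])


def make_learner(name: str, seed: int = 0, fast: bool = False):
    """Instantiate a learner by its scan name.

    Tree and NB learners see raw features; distance-based learners (kNN, PNN,
    MLP) are wrapped in a standardiser fitted on training folds only.
    Recognised names: ``rf``, ``xgb``, ``nb``, ``mlp``, ``pnn``,
    ``knn(k=K)`` and ``knn-wd(k=K)`` (distance-weighted).
    """
    if name == "rf":
        return RandomForestClassifier(
            n_estimators=60 if fast else 200,
            random_state=seed,
            n_jobs=1,
        )
    if name == "xgb":
        # gradient-boosted trees (the XGBoost algorithm family)
        return HistGradientBoostingClassifier(
            max_iter=60 if fast else 150,
            random_state=seed,
        )
    if name == "nb":
        return GaussianNB()
    if name == "mlp":
        return _scaled(
            MLPClassifier(
                hidden_layer_sizes=(50,),
                max_iter=200 if fast else 500,
                random_state=seed,
            )
        )
    if name == "pnn":
        return _scaled(PNNClassifier(random_state=seed))
    if name.startswith("knn"):
        weighted = name.startswith("knn-wd")
        k = 5
        if "(" in name:
            k = int(name.split("k=")[1].rstrip(")"))
        return _scaled(
            KNeighborsClassifier(
                n_neighbors=k, weights="distance" if weighted else "uniform"
            )
        )
    raise ValueError(f"unknown learner {name!r}")


def expand_learner_names(names: Sequence[str], knn_ks: Sequence[int] = (1, 3, 5, 7, 9)):
    """Expand bare ``knn`` into its neighbour-count / weighting variants."""
    out: list[str] = []
    for name in names:
        if name == "knn":
            out.extend(f"knn(k={k})" for k in knn_ks)
            out.extend(f"knn-wd(k={k})" for k in knn_ks)
        else:
            out.append(name)
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    learner_name: str
    consensus_level: int | None
    accuracy_cv: float
    kappa_cv: float
    accuracy_test: float
    kappa_test: float
    params: dict = field(default_factory=dict)


def cv_metrics(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    n_splits: int = DEFAULT_CV_FOLDS,
    groups: np.ndarray | None = None,
) -> tuple[float, float]:
    """(accuracy, kappa) from leave-(1/n_splits)-out cross-validated predictions.

    Pose-level folds by default; pass ``groups`` for compound-grouped folds
    (leakage-safe variant, flagged in reports by the caller).
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if groups is not None:
        cv = GroupKFold(n_splits=min(n_splits, len(np.unique(groups))))
        pred = cross_val_predict(clone(estimator), X, y, cv=cv, groups=groups)
    else:
        cv = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
        pred = cross_val_predict(clone(estimator), X, y, cv=cv)
    counts = ConfusionCounts.from_labels(y, pred)
    return accuracy(counts), cohens_kappa(counts)


def holdout_metrics(estimator, X_test, y_test) -> tuple[float, float]:
    pred = estimator.predict(X_test)
    counts = ConfusionCounts.from_labels(y_test, pred)
    return accuracy(counts), cohens_kappa(counts)


def partition_rows(matrix: FeatureMatrix, split: SplitAssignment):
    """(train_mask, test_mask) over matrix rows via each pose's compound."""
    train = np.array(
        [matrix.compound_of[p] in split.training_compounds for p in matrix.pose_ids]
    )
    test = np.array(
        [matrix.compound_of[p] in split.testing_compounds for p in matrix.pose_ids]
    )
    return train, test


def scan_learners(
    matrix: FeatureMatrix,
    split: SplitAssignment,
    learners: Sequence[str] = ("rf", "xgb", "nb", "knn", "pnn", "mlp"),
    seed: int = 0,
    consensus_level: int | None = None,
    drop_intermediates: bool = True,
    grouped_cv: bool = False,
    fast: bool = False,
    knn_ks: Sequence[int] = (1, 3, 5, 7, 9),
) -> list[EvalReport]:
    """Evaluate each learner by training-partition CV plus external testing.

    Returns reports sorted by ``kappa_test`` (best first).  Intermediates are
    excluded by default (binary active/inactive task); retain them for the
    3-class variant.
    """
    data = matrix.drop_class(INTERMEDIATE) if drop_intermediates else matrix
    train_mask, test_mask = partition_rows(data, split)
    X, y = data.X, data.y()
    X_train, y_train = X[train_mask], y[train_mask]
    X_test, y_test = X[test_mask], y[test_mask]
    if len(np.unique(y_train)) < 2:
        raise ValueError("training partition contains a single class")
    groups = data.groups()[train_mask] if grouped_cv else None

    reports = []
    for name in expand_learner_names(learners, knn_ks):
        estimator = make_learner(name, seed=seed, fast=fast)
        acc_cv, kap_cv = cv_metrics(estimator, X_train, y_train, seed=seed, groups=groups)
        fitted = clone(estimator).fit(X_train, y_train)
        acc_te, kap_te = holdout_metrics(fitted, X_test, y_test)
        reports.append(
            EvalReport(
                learner_name=name,
                consensus_level=consensus_level,
                accuracy_cv=acc_cv,
                kappa_cv=kap_cv,
                accuracy_test=acc_te,
                kappa_test=kap_te,
                params={"seed": seed, "grouped_cv": grouped_cv, "fast": fast},
            )
        )
    reports.sort(key=lambda r: -r.kappa_test)
    return reports
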