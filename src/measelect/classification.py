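"""Stimulation-site decoding from population response patterns.

Three decoders over per-stimulus feature vectors (activation-time pattern,
total-spike-count pattern, first-bin spike rate, or the full electrodes x
bins pattern):

* ``kmeans`` — unsupervised two-cluster K-means; clusters matched to the
  site labels by maximum agreement; accuracy = matched fraction;
* ``kmeans_pc`` — K-means with predefined centroids: each class centroid is
  the mean of that class's rows, rows assigned to the nearest centroid
  (resubstitution by default; a held-out variant is available);
* ``svc`` — supervised RBF-kernel support-vector classifier, kernel width
  and regularization chosen by an inner fivefold grid search, accuracy
  reported by outer fivefold cross-validation.

Also provides the electrode-exclusion accuracy curves: iteratively removing
the lowest- (or highest-) overlap electrode and re-estimating kmeans_pc
accuracy on total-spike-count patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import WindowSpec
from .features import ResponsePattern

__all__ = [
    "FeatureMatrix",
    "ClassificationReport",
    "ExclusionCurve",
    "build_feature_matrix",
    "kmeans_classify",
    "kmeans_pc_classify",
    "svc_classify",
    "electrode_exclusion_curve",
]

FEATURES = ("activation", "tsc", "first_bin", "full")


@dataclass
class FeatureMatrix:
    """Stimuli x features matrix with per-row site labels."""

    x: np.ndarray
    labels: np.ndarray
    feature: str
    electrode_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.x.ndim != 2 or self.x.shape[0] != self.labels.shape[0]:
            raise ValueError("x must be 2-d with one label per row")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def build_feature_matrix(
    patterns: list[ResponsePattern],
    feature: str = "tsc",
    window: WindowSpec | None = None,
    electrodes: np.ndarray | None = None,
) -> FeatureMatrix:
    """Assemble per-stimulus feature vectors.

    ``electrodes`` restricts the columns to a subset (boolean mask or 1-based
    id array).  Missing activation times (electrode silent on a stimulus) are
    imputed with the window upper bound — "no response" is informatively
    late.
    """
    if feature not in FEATURES:
        raise ValueError(f"feature must be one of {FEATURES}")
    if not patterns:
        raise ValueError("no patterns")
    n_e = patterns[0].n_electrodes
    if electrodes is None:
        keep = np.arange(n_e)
    else:
        electrodes = np.asarray(electrodes)
        keep = np.nonzero(electrodes)[0] if electrodes.dtype == bool else electrodes - 1
    labels = np.array([p.site for p in patterns], dtype=object)
    if feature == "activation":
        window = window or WindowSpec()
        x = np.stack([p.activation_time[keep] for p in patterns])
        x = np.where(np.isnan(x), window.response_window, x)
    elif feature == "tsc":
        x = np.stack([p.total_spike_count[keep] for p in patterns]).astype(float)
    elif feature == "first_bin":
        x = np.stack([p.counts[keep, 0] for p in patterns]).astype(float)
    else:
        x = np.stack([p.counts[keep].ravel() for p in patterns]).astype(float)
    return FeatureMatrix(x, labels, feature, electrode_ids=keep + 1)


@dataclass
class ClassificationReport:
    method: str
    feature: str
    accuracy: float  # percent
    confusion: np.ndarray  # (n_classes, n_classes), rows = true
    per_fold: list[float] | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.accuracy <= 100 or not np.isfinite(self.accuracy):
            raise ValueError("accuracy must lie in [0, 100]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "feature": self.feature,
            "accuracy": float(self.accuracy),
            "confusion": self.confusion.tolist(),
            "per_fold": self.per_fold,
            "details": self.details,
        }


def _require_two_classes(fm: FeatureMatrix, min_per_class: int = 2) -> None:
    classes, counts = np.unique(fm.labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {list(classes)}")
    if counts.min() < min_per_class:
        raise ValueError(f"each class needs at least {min_per_class} rows")


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1
    return conf


def kmeans_classify(fm: FeatureMatrix, random_state: int = 0, n_init: int = 10) -> ClassificationReport:
    """Unsupervised k = 2 clustering; accuracy is the best label matching."""
    _require_two_classes(fm)
    classes = fm.classes
    km = KMeans(n_clusters=2, n_init=n_init, random_state=random_state)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*smaller than n_clusters.*")
        assign = km.fit_predict(fm.x)
    y_bin = (fm.labels == classes[1]).astype(int)
    agree = int(np.sum(assign == y_bin))
    if agree >= len(y_bin) - agree:
        pred_bin = assign
    else:
        pred_bin = 1 - assign
    y_pred = classes[pred_bin]
    acc = 100.0 * np.mean(y_pred == fm.labels)
    return ClassificationReport(
        "kmeans", fm.feature, float(acc), _confusion(fm.labels, y_pred, classes)
    )


def kmeans_pc_classify(
    fm: FeatureMatrix,
    holdout_frac: float | None = None,
    random_state: int = 0,
) -> ClassificationReport:
    """Nearest-centroid assignment with class-mean centroids.

    By default centroids are computed on all rows and accuracy is
    resubstitution (reported as such in ``details``).  With
    ``holdout_frac`` the centroids come from a stratified training split and
    accuracy is measured on the held-out rows.
    """
    _require_two_classes(fm)
    classes = fm.classes
    if holdout_frac is None:
        train_idx = test_idx = np.arange(len(fm.labels))
        mode = "resubstitution"
    else:
        if not 0 < holdout_frac < 1:
            raise ValueError("holdout_frac must lie in (0, 1)")
        rng = np.random.default_rng(random_state)
        train_parts = []
        for c in classes:
            idx = np.nonzero(fm.labels == c)[0]
            n_train = max(1, int(round((1 - holdout_frac) * len(idx))))
            train_parts.append(rng.permutation(idx)[:n_train])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.setdiff1d(np.arange(len(fm.labels)), train_idx)
        mode = "holdout"
    centroids = np.stack(
        [fm.x[train_idx][fm.labels[train_idx] == c].mean(axis=0) for c in classes]
    )
    d = np.linalg.norm(fm.x[test_idx][:, None, :] - centroids[None, :, :], axis=2)
    y_pred = classes[np.argmin(d, axis=1)]
    y_true = fm.labels[test_idx]
    acc = 100.0 * np.mean(y_pred == y_true)
    return ClassificationReport(
        "kmeans_pc",
        fm.feature,
        float(acc),
        _confusion(y_true, y_pred, classes),
        details={"mode": mode},
    )


def _median_gamma(x: np.ndarray, rng: np.random.Generator) -> float:
    """Median-heuristic RBF width on (standardized) features."""
    n = x.shape[0]
    if n > 200:
        x = x[rng.choice(n, 200, replace=False)]
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=2)
    med = float(np.median(d2[np.triu_indices_from(d2, k=1)]))
    return 1.0 / med if med > 0 else 1.0


def svc_classify(
    fm: FeatureMatrix,
    folds: int = 5,
    random_state: int = 0,
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0),
) -> ClassificationReport:
    """RBF support-vector classification with nested cross-validation.

    Outer stratified ``folds``-fold CV gives the reported accuracy; within
    each training fold a grid over C and gamma (median heuristic x
    {0.1, 1, 10}) is selected by an inner stratified ``folds``-fold CV.
    Features are z-scored using training-fold statistics.
    """
    _require_two_classes(fm, min_per_class=folds)
    classes = fm.classes
    rng = np.random.default_rng(random_state)
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    y = fm.labels.astype(str)
    per_fold: list[float] = []
    y_pred = np.empty(len(y), dtype=object)
    best_params: list[dict] = []
    for train, test in outer.split(fm.x, y):
        scaler = StandardScaler().fit(fm.x[train])
        x_tr = scaler.transform(fm.x[train])
        x_te = scaler.transform(fm.x[test])
        g0 = _median_gamma(x_tr, rng)
        inner = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
        grid = GridSearchCV(
            SVC(kernel="rbf"),
            {"C": list(c_grid), "gamma": [0.1 * g0, g0, 10 * g0]},
            cv=inner,
            n_jobs=None,
        )
        grid.fit(x_tr, y[train])
        pred = grid.predict(x_te)
        y_pred[test] = pred
        per_fold.append(100.0 * float(np.mean(pred == y[test])))
        best_params.append(grid.best_params_)
    acc = 100.0 * float(np.mean(y_pred == fm.labels))
    return ClassificationReport(
        "svc",
        fm.feature,
        acc,
        _confusion(fm.labels, y_pred, classes),
        per_fold=per_fold,
        details={"folds": folds, "best_params": best_params},
    )


@dataclass
class ExclusionCurve:
    """kmeans_pc accuracy as electrodes are removed by overlap extremity.

    Point i has ``n_retained[i]`` electrodes; ``removed_before[i]`` is the
    electrode id removed to reach that point (None for the first, full-set
    point).  Sizes run from n down to 2, giving n - 1 points.
    """

    direction: str
    n_retained: np.ndarray
    accuracy: np.ndarray
    removed_before: list[int | None]


def electrode_exclusion_curve(
    patterns: list[ResponsePattern],
    electrode_overlaps: np.ndarray,
    direction: str = "drop_lowest",
    feature: str = "tsc",
    window: WindowSpec | None = None,
    random_state: int = 0,
) -> ExclusionCurve:
    """Iteratively remove the extreme-overlap electrode, re-estimating
    kmeans_pc accuracy at each step down to two electrodes.

    ``electrode_overlaps`` is a per-electrode vector (1-based positionally);
    NaN entries mark electrodes excluded from the analysis altogether.
    ``direction='drop_lowest'`` removes the most selective (lowest-overlap)
    electrode first; ``'drop_highest'`` the least selective.
    """
    if direction not in ("drop_lowest", "drop_highest"):
        raise ValueError("direction must be 'drop_lowest' or 'drop_highest'")
    electrode_overlaps = np.asarray(electrode_overlaps, dtype=float)
    eligible = np.nonzero(np.isfinite(electrode_overlaps))[0]
    if eligible.size < 3:
        raise ValueError("need at least 3 electrodes with defined overlaps")
    order = eligible[np.argsort(electrode_overlaps[eligible], kind="stable")]
    if direction == "drop_highest":
        order = order[::-1]
    remaining = list(order)
    n_retained: list[int] = []
    accuracy: list[float] = []
    removed: list[int | None] = []
    last_removed: int | None = None
    while len(remaining) >= 2:
        fm = build_feature_matrix(
            patterns, feature=feature, window=window, electrodes=np.array(remaining) + 1
        )
        rep = kmeans_pc_classify(fm, random_state=random_state)
        n_retained.append(len(remaining))
        accuracy.append(rep.accuracy)
        removed.append(last_removed)
        last_removed = int(remaining[0] + 1)
        remaining = remaining[1:]
    return ExclusionCurve(
        direction=direction,
        n_retained=np.asarray(n_retained),
        accuracy=np.asarray(accuracy),
        removed_before=removed,
    )
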