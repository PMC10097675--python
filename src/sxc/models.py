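"""Classifier training protocol: Tanimoto kernel, metrics, random grid search.

Both algorithms are trained on identical balanced splits.  Hyperparameters
are chosen by random grid search ranked on validation MCC; exact MCC ties
are broken by a loss function (log loss for RF, hinge loss for SVM).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from sxc.seeding import derive_rng

__all__ = [
    "RF_GRID",
    "SVM_GRID",
    "default_grid",
    "PerformanceReport",
    "TrainedModel",
    "tanimoto_kernel",
    "compute_metrics",
    "evaluate_predictions",
    "tie_break_loss",
    "expand_grid",
    "train_model_with_search",
]

# Default hyperparameter grids.  The SVM C list is deduplicated to its 14
# distinct values.
RF_GRID: Mapping[str, Sequence[Any]] = {
    "n_estimators": (100, 500),
    "criterion": ("gini", "entropy"),
    "min_samples_split": (2, 3, 4, 5),
    "max_features": ("sqrt", "log2"),
    "bootstrap": (True, False),
}

SVM_GRID: Mapping[str, Sequence[Any]] = {
    "C": (0.1, 1, 10, 50, 100, 200, 400, 500, 750, 1000, 2500, 5000, 7500, 10000),
    "tol": (1e-3, 1e-2, 0.1, 1, 2, 3),
}


def default_grid(algorithm: str) -> Mapping[str, Sequence[Any]]:
    if algorithm == "RF":
        return dict(RF_GRID)
    if algorithm == "SVM":
        return dict(SVM_GRID)
    raise ValueError(f"unknown algorithm: {algorithm!r}")


def tanimoto_kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity ``K[i, j] = |x_i & y_j| / |x_i | y_j|``.

    Inputs must be binary matrices with equal feature dimension.  The 0/0
    case (two all-zero vectors) is defined as 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.ndim == 1:
        a = a[None, :]
    if b.ndim == 1:
        b = b[None, :]
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions differ")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("inputs must be binary")
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    common = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - common
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(union > 0, common / np.where(union > 0, union, 1.0), 0.0)
    return k


@dataclass(frozen=True)
class PerformanceReport:
    tp: int
    tn: int
    fp: int
    fn: int
    mcc: float
    ba: float
    f1: float


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> PerformanceReport:
    """MCC, balanced accuracy and F1 from confusion counts.

    MCC is defined as 0 whenever any factor of its denominator vanishes.
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("confusion counts sum to zero")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    ba = 0.5 * (sens + spec)
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return PerformanceReport(tp, tn, fp, fn, mcc, ba, f1)


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> PerformanceReport:
    """Confusion-count metrics with label 1 as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return compute_metrics(tp, tn, fp, fn)


_LOG_EPS = 1e-15  # probability clipping in log loss


def tie_break_loss(algorithm: str, truths: np.ndarray, outputs: np.ndarray) -> float:
    """Mean tie-breaker loss: log loss for RF, hinge loss for SVM.

    RF: ``truths`` in {0, 1}, ``outputs`` are probabilities of label 1.
    SVM: ``truths`` in {-1, 1}, ``outputs`` are decision-function values.
    """
    truths = np.asarray(truths, dtype=np.float64)
    outputs = np.asarray(outputs, dtype=np.float64)
    if truths.shape != outputs.shape:
        raise ValueError("length mismatch between truths and outputs")
    if algorithm == "RF":
        if not np.isin(truths, (0.0, 1.0)).all():
            raise ValueError("RF truths must be in {0, 1}")
        p = np.clip(outputs, _LOG_EPS, 1.0 - _LOG_EPS)
        return float(np.mean(-(truths * np.log(p) + (1 - truths) * np.log(1 - p))))
    if algorithm == "SVM":
        if not np.isin(truths, (-1.0, 1.0)).all():
            raise ValueError("SVM truths must be in {-1, 1}")
        return float(np.mean(np.maximum(0.0, 1.0 - truths * outputs)))
    raise ValueError(f"unknown algorithm: {algorithm!r}")


@dataclass
class TrainedModel:
    """A fitted classifier with its search outcome and retained training data.

    The training fingerprints/labels are retained deliberately: SVM kernel
    evaluation at prediction time and the Shapley background both need them.
    ``classes`` is sorted alphabetically; class index 1 is encoded as label 1
    ({0, 1}) and +1 ({-1, +1}).
    """

    algorithm: str
    estimator: Any
    params: dict[str, Any]
    classes: tuple[str, str]
    x_train: np.ndarray
    y_train: np.ndarray
    validation_mcc: float
    tie_break: float
    seed: int
    search_log: list[dict[str, Any]] = field(default_factory=list, repr=False)

    def encode_labels(self, labels: Sequence[str]) -> np.ndarray:
        lut = {self.classes[0]: 0, self.classes[1]: 1}
        try:
            return np.array([lut[l] for l in labels], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"unknown class label: {exc}") from exc

    def decode_labels(self, y: np.ndarray) -> list[str]:
        return [self.classes[int(v)] for v in y]

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.algorithm == "SVM":
            return self.estimator.predict(tanimoto_kernel(x, self.x_train))
        return self.estimator.predict(x)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.algorithm != "RF":
            raise ValueError("probabilities are defined for RF models only")
        return self.estimator.predict_proba(x)

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        if self.algorithm != "SVM":
            raise ValueError("decision values are defined for SVM models only")
        return self.estimator.decision_function(tanimoto_kernel(x, self.x_train))

    def evaluate(self, x: np.ndarray, labels: Sequence[str]) -> PerformanceReport:
        return evaluate_predictions(self.encode_labels(labels), self.predict(x))


def expand_grid(grid: Mapping[str, Sequence[Any]]) -> list[dict[str, Any]]:
    """All hyperparameter settings of a grid, in deterministic order."""
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _fit_one(algorithm, params, x_train, y_train, k_train, seed):
    if algorithm == "RF":
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        est.fit(x_train, y_train)
    else:
        est = SVC(kernel="precomputed", **params)
        est.fit(k_train, y_train)
    return est


def train_model_with_search(
    x_train: np.ndarray,
    labels_train: Sequence[str],
    x_val: np.ndarray,
    labels_val: Sequence[str],
    algorithm: str,
    grid: Mapping[str, Sequence[Any]] | None = None,
    n_search: int = 50,
    seed: int = 0,
) -> TrainedModel:
    """Random grid search: sample up to ``n_search`` settings without
    replacement, rank by validation MCC, break exact ties by loss, then by
    sampling order."""
    if algorithm not in ("RF", "SVM"):
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    if n_search < 1:
        raise ValueError("n_search must be >= 1")
    classes = tuple(sorted(set(labels_train)))
    if len(classes) != 2:
        raise ValueError(f"training set must contain exactly 2 classes, got {classes}")

    lut = {classes[0]: 0, classes[1]: 1}
    y_train = np.array([lut[l] for l in labels_train], dtype=np.int64)
    y_val = np.array([lut[l] for l in labels_val], dtype=np.int64)

    settings = expand_grid(default_grid(algorithm) if grid is None else grid)
    rng = derive_rng(seed, "grid-search", algorithm)
    order = rng.permutation(len(settings))[: min(n_search, len(settings))]

    k_train = tanimoto_kernel(x_train, x_train) if algorithm == "SVM" else None
    k_val = tanimoto_kernel(x_val, x_train) if algorithm == "SVM" else None

    best = None
    search_log = []
    for rank, idx in enumerate(order):
        params = settings[int(idx)]
        fit_seed = int(derive_rng(seed, "fit", algorithm, rank).integers(2**31 - 1))
        est = _fit_one(algorithm, params, x_train, y_train, k_train, fit_seed)
        if algorithm == "RF":
            y_pred = est.predict(x_val)
            outputs = est.predict_proba(x_val)[:, list(est.classes_).index(1)]
            loss = tie_break_loss("RF", y_val, outputs)
        else:
            y_pred = est.predict(k_val)
            outputs = est.decision_function(k_val)
            loss = tie_break_loss("SVM", 2.0 * y_val - 1.0, outputs)
        mcc = evaluate_predictions(y_val, y_pred).mcc
        search_log.append({"rank": rank, "params": params, "mcc": mcc, "loss": loss,
                           "fit_seed": fit_seed})
        key = (-mcc, loss, rank)
        if best is None or key < best[0]:
            best = (key, est, params, mcc, loss, fit_seed)

    _, est, params, mcc, loss, fit_seed = best
    return TrainedModel(
        algorithm=algorithm,
        estimator=est,
        params=dict(params),
        classes=classes,  # type: ignore[arg-type]
        x_train=np.asarray(x_train),
        y_train=y_train,
        validation_mcc=mcc,
        tie_break=loss,
        seed=fit_seed,
        search_log=search_log,
    )
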