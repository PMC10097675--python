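"""Analysis layer: prediction patterns, cumulative Shapley values and scores.

Prediction patterns are per-compound correctness bit vectors across the
training-size schedule, classified into five categories.  Instance-based
cumulative Shapley values split each oriented explanation into sums over
present and absent fingerprint positions; feature-based cumulative values
aggregate per-instance-normalized attributions per feature.  The feature
contribution score f_cs, its Pearson correlation with model MCC, and
combined PCCs diagnose the feature-contribution regime (FC_pattern) of
each algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from sxc.shapley.explanation import ShapleyExplanation

__all__ = [
    "PATTERN_CATEGORIES",
    "classify_prediction_pattern",
    "pattern_tabulate",
    "InstanceCumulative",
    "instance_cumulative",
    "feature_contribution_score",
    "pearson_cc",
    "combined_pcc",
    "classify_fc_pattern",
    "FeatureCumulative",
    "feature_cumulative",
    "top_k_features",
    "top_k_feature_intersection",
]

PATTERN_CATEGORIES = (
    "consistently_correct",
    "consistently_incorrect",
    "start_correct_end_incorrect",
    "start_incorrect_end_correct",
    "variable",
)


def classify_prediction_pattern(bits: Sequence[int]) -> str:
    """Classify a correctness bit vector into one of the five categories.

    All ones / all zeros are the consistent categories; a single switch
    (1^k 0^(n-k) or 0^k 1^(n-k), 1 <= k <= n-1) is a start/end category;
    anything else is variable.
    """
    arr = np.asarray(bits)
    if arr.size == 0:
        raise ValueError("bits must be non-empty")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("bits must be binary")
    arr = arr.astype(np.int8)
    if arr.all():
        return "consistently_correct"
    if not arr.any():
        return "consistently_incorrect"
    switches = int(np.abs(np.diff(arr)).sum())
    if switches == 1:
        return "start_correct_end_incorrect" if arr[0] == 1 else "start_incorrect_end_correct"
    return "variable"


def pattern_tabulate(patterns: pd.DataFrame) -> pd.DataFrame:
    """Table-2-style tabulation of prediction patterns for RF vs. SVM.

    ``patterns`` needs columns compound_id, pair, trial, algorithm, category.
    Both algorithms must cover identical (compound_id, pair, trial) keys.
    Per category: #patterns counts key occurrences, #compounds counts
    distinct compound ids, and the intersection counts keys on which both
    algorithms fall in that category (with the percentage of the RF count).
    """
    required = {"compound_id", "pair", "trial", "algorithm", "category"}
    if not required <= set(patterns.columns):
        raise ValueError(f"patterns must have columns {sorted(required)}")
    keys = ["compound_id", "pair", "trial"]
    by_algo = {
        algo: grp.set_index(keys)["category"]
        for algo, grp in patterns.groupby("algorithm")
    }
    if set(by_algo) != {"RF", "SVM"}:
        raise ValueError("patterns must contain both RF and SVM records")
    rf, svm = by_algo["RF"], by_algo["SVM"]
    if not rf.index.sort_values().equals(svm.index.sort_values()):
        raise ValueError("RF and SVM must cover identical (compound, pair, trial) keys")
    svm = svm.reindex(rf.index)

    rows = []
    for cat in PATTERN_CATEGORIES:
        in_rf = rf == cat
        in_svm = svm == cat
        n_rf = int(in_rf.sum())
        n_svm = int(in_svm.sum())
        inter = int((in_rf & in_svm).sum())
        cpds_rf = rf.index.get_level_values("compound_id")[in_rf].nunique()
        cpds_svm = svm.index.get_level_values("compound_id")[in_svm].nunique()
        cpds_inter = rf.index.get_level_values("compound_id")[in_rf & in_svm].nunique()
        rows.append(
            {
                "category": cat,
                "rf_patterns": n_rf,
                "svm_patterns": n_svm,
                "intersection_patterns": inter,
                "intersection_pct": 100.0 * inter / n_rf if n_rf else 0.0,
                "rf_compounds": int(cpds_rf),
                "svm_compounds": int(cpds_svm),
                "intersection_compounds": int(cpds_inter),
                "intersection_compounds_pct": 100.0 * cpds_inter / cpds_rf if cpds_rf else 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class InstanceCumulative:
    """Per-compound sums of oriented attributions over present/absent bits."""

    compound_id: str
    cs_present: float
    cs_absent: float


def instance_cumulative(expl: ShapleyExplanation, x: np.ndarray) -> InstanceCumulative:
    x = np.asarray(x)
    if x.shape[0] != expl.values.shape[0]:
        raise ValueError("fingerprint / explanation length mismatch")
    present = x == 1
    return InstanceCumulative(
        compound_id=expl.compound_id,
        cs_present=float(expl.values[present].sum()),
        cs_absent=float(expl.values[~present].sum()),
    )


def feature_contribution_score(cumulatives: Sequence[InstanceCumulative]) -> float | None:
    """f_cs = median(cs_present) - median(cs_absent) over correctly predicted
    compounds of one class under one model; None when no compounds qualify."""
    if not cumulatives:
        return None
    present = np.array([c.cs_present for c in cumulatives])
    absent = np.array([c.cs_absent for c in cumulatives])
    return float(np.median(present) - np.median(absent))


def pearson_cc(xs: Sequence[float], ys: Sequence[float]) -> float | None:
    """Product-moment correlation; None when either variance is zero."""
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.shape != ys.shape:
        raise ValueError("length mismatch")
    if xs.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def combined_pcc(pcc1: float | None, pcc2: float | None, algorithm: str) -> float | None:
    """RF: |PCC1| + |PCC2|; SVM: PCC1 + PCC2.  None propagates."""
    if algorithm not in ("RF", "SVM"):
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    if pcc1 is None or pcc2 is None:
        return None
    if algorithm == "RF":
        return abs(pcc1) + abs(pcc2)
    return pcc1 + pcc2


def classify_fc_pattern(
    pcc1: float | None,
    pcc2: float | None,
    combined: float | None,
    algorithm: str,
    threshold: float = 1.0,
    invert: bool = False,
) -> int:
    """FC_pattern: 1 = present-or-absent (RF only), 2 = present-and-absent,
    3 = only-present (SVM only).

    Default mapping: a combined PCC at or above the threshold selects the
    algorithm-specific pattern (1 for RF, 3 for SVM), otherwise pattern 2.
    ``invert`` flips the threshold orientation (the published threshold
    semantics are ambiguous; this keeps both readings available).
    """
    if algorithm not in ("RF", "SVM"):
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    if combined is None:
        raise ValueError("combined PCC undefined")
    above = combined >= threshold
    if invert:
        above = not above
    if algorithm == "RF":
        return 1 if above else 2
    return 3 if above else 2


@dataclass
class FeatureCumulative:
    """Per-(predicted class, feature, status) sums of normalized attributions.

    ``present_sum[c]`` / ``absent_sum[c]`` are length-``n_features`` vectors;
    counts record how often each feature occurred with that status among the
    aggregated (correctly predicted) instances.
    """

    n_features: int
    present_sum: dict[str, np.ndarray] = field(default_factory=dict)
    absent_sum: dict[str, np.ndarray] = field(default_factory=dict)
    present_count: dict[str, np.ndarray] = field(default_factory=dict)
    absent_count: dict[str, np.ndarray] = field(default_factory=dict)
    n_instances: dict[str, int] = field(default_factory=dict)
    n_skipped: int = 0

    def _ensure(self, cls: str) -> None:
        if cls not in self.present_sum:
            self.present_sum[cls] = np.zeros(self.n_features)
            self.absent_sum[cls] = np.zeros(self.n_features)
            self.present_count[cls] = np.zeros(self.n_features, dtype=np.int64)
            self.absent_count[cls] = np.zeros(self.n_features, dtype=np.int64)
            self.n_instances[cls] = 0

    def add(self, other: "FeatureCumulative") -> None:
        if other.n_features != self.n_features:
            raise ValueError("feature dimension mismatch")
        for cls in other.present_sum:
            self._ensure(cls)
            self.present_sum[cls] += other.present_sum[cls]
            self.absent_sum[cls] += other.absent_sum[cls]
            self.present_count[cls] += other.present_count[cls]
            self.absent_count[cls] += other.absent_count[cls]
            self.n_instances[cls] += other.n_instances[cls]
        self.n_skipped += other.n_skipped


def feature_cumulative(
    explanations: Sequence[ShapleyExplanation],
    fingerprints: np.ndarray,
    correct: Sequence[bool],
    predicted_classes: Sequence[str],
) -> FeatureCumulative:
    """Aggregate per-instance-normalized attributions per feature and status.

    Only correctly predicted instances are aggregated.  Each instance's
    oriented attribution vector is divided by its absolute sum (instances
    with zero absolute sum are skipped and counted), so every aggregated
    vector has absolute-value sum exactly 1.
    """
    fingerprints = np.atleast_2d(np.asarray(fingerprints))
    if len(explanations) != fingerprints.shape[0]:
        raise ValueError("explanations / fingerprints length mismatch")
    result = FeatureCumulative(n_features=fingerprints.shape[1])
    for expl, x, ok, cls in zip(explanations, fingerprints, correct, predicted_classes):
        if not ok:
            continue
        total = float(np.abs(expl.values).sum())
        if total == 0.0:
            result.n_skipped += 1
            continue
        normalized = expl.values / total
        result._ensure(cls)
        present = x == 1
        result.present_sum[cls][present] += normalized[present]
        result.absent_sum[cls][~present] += normalized[~present]
        result.present_count[cls][present] += 1
        result.absent_count[cls][~present] += 1
        result.n_instances[cls] += 1
    return result


def top_k_features(values: np.ndarray, k: int = 15) -> list[int]:
    """Indices of the k largest values, descending; ties broken by index."""
    values = np.asarray(values, dtype=np.float64)
    order = np.lexsort((np.arange(values.size), -values))
    return [int(i) for i in order[:k]]


def top_k_feature_intersection(
    per_model_values: Mapping[object, Mapping[tuple[str, str], np.ndarray]],
    k: int = 15,
) -> dict[tuple[str, str], set[int]]:
    """Intersection of top-k feature sets across models, per (class, status).

    ``per_model_values[model][(class, status)]`` is a cumulative-value vector
    (status in {"present", "absent"}).  When fewer than k features have a
    nonzero cumulative value, all nonzero features are used instead.
    """
    if len(per_model_values) < 2:
        raise ValueError("need at least two models to intersect")
    keys: set[tuple[str, str]] = set()
    for tables in per_model_values.values():
        keys |= set(tables)
    out: dict[tuple[str, str], set[int]] = {}
    for key in sorted(keys):
        sets = []
        for tables in per_model_values.values():
            values = np.asarray(tables.get(key, np.zeros(0)), dtype=np.float64)
            eligible = int((values != 0).sum())
            sets.append(set(top_k_features(values, min(k, eligible))))
        out[key] = set.intersection(*sets) if sets else set()
    return out
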