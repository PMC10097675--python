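"""Compound-record filters and similarity-based activity-class selection.

Records are kept only when every assay annotation has the maximum
confidence score, the molecular mass lies in the accepted window, at least
one Kd/Ki/IC50 annotation marks the compound as active, no annotation marks
it inactive (inconsistent records are discarded), and no interference /
aggregator / rule-violation flag is set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sxc.models import tanimoto_kernel
from sxc.synthetic import (
    MASS_RANGE,
    POTENCY_THRESHOLD,
    POTENCY_TYPES,
    REQUIRED_CONFIDENCE,
    CompoundRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "REJECTION_ORDER",
    "curate_records",
    "curation_reason",
    "select_classes_by_similarity",
    "ClassSimilarity",
]

#: fixed order in which violations are checked; a rejection reports the first hit
REJECTION_ORDER = (
    "no-potency",
    "mass-range",
    "confidence",
    "low-potency",
    "inconsistent-potency",
    "interference",
    "aggregator",
    "rule-violation",
)


def curation_reason(record: CompoundRecord) -> str | None:
    """First violated curation rule in :data:`REJECTION_ORDER`, or None if clean."""
    potency_anns = [a for a in record.potency_annotations if a.type in POTENCY_TYPES]
    if not potency_anns:
        return "no-potency"
    if not MASS_RANGE[0] <= record.molecular_mass <= MASS_RANGE[1]:
        return "mass-range"
    if any(a.confidence != REQUIRED_CONFIDENCE for a in record.potency_annotations):
        return "confidence"
    active = [a for a in potency_anns if a.ppot > POTENCY_THRESHOLD]
    inactive = [a for a in potency_anns if a.ppot <= POTENCY_THRESHOLD]
    if not active:
        return "low-potency"
    if inactive:
        return "inconsistent-potency"
    if record.interference_flag:
        return "interference"
    if record.aggregator_flag:
        return "aggregator"
    if record.rule_violation_flag:
        return "rule-violation"
    return None


def curate_records(
    records: Sequence[CompoundRecord],
) -> tuple[list[CompoundRecord], list[tuple[CompoundRecord, str]]]:
    """Split records into (kept, rejected-with-reason).

    Conservation: ``len(kept) + len(rejected) == len(records)``.  Idempotent:
    curating the kept list again rejects nothing.
    """
    if not records:
        raise ValueError("records must be non-empty")
    kept: list[CompoundRecord] = []
    rejected: list[tuple[CompoundRecord, str]] = []
    for rec in records:
        reason = curation_reason(rec)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return kept, rejected


@dataclass(frozen=True)
class ClassSimilarity:
    class_id: str
    n_compounds: int
    intra: float
    inter: float

    @property
    def difference(self) -> float:
        return self.intra - self.inter


def _mean_offdiag(k: np.ndarray) -> float:
    n = k.shape[0]
    if n < 2:
        return float("nan")
    iu = np.triu_indices(n, k=1)
    return float(k[iu].mean())


def select_classes_by_similarity(
    classes: Mapping[str, np.ndarray],
    k_omit: int,
    min_size: int = 1000,
    statistic: str = "mean",
) -> tuple[list[str], pd.DataFrame]:
    """Drop the ``k_omit`` classes with the largest intra-minus-inter Tanimoto gap.

    For each qualifying class (``>= min_size`` compounds), ``intra`` is the
    summary statistic of all within-class pairwise Tanimoto similarities and
    ``inter`` the statistic of similarities against the pooled union of all
    other classes.  Classes are ranked by ``intra - inter`` descending (ties
    broken by lexicographic class id, smallest omitted first) and the top
    ``k_omit`` are omitted.  Returns the selected class ids (sorted) and the
    full similarity table.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    reduce = np.mean if statistic == "mean" else np.median

    qualifying = {}
    for cid in sorted(classes):
        mat = np.asarray(classes[cid])
        if mat.shape[0] < min_size:
            logger.info("class %s below size threshold (%d < %d); excluded",
                        cid, mat.shape[0], min_size)
            continue
        qualifying[cid] = mat
    if len(qualifying) < k_omit + 2:
        raise ValueError(
            f"need at least {k_omit + 2} qualifying classes, got {len(qualifying)}"
        )

    rows = []
    for cid, mat in qualifying.items():
        intra_k = tanimoto_kernel(mat, mat)
        n = mat.shape[0]
        if statistic == "mean":
            intra = _mean_offdiag(intra_k)
        else:
            iu = np.triu_indices(n, k=1)
            intra = float(np.median(intra_k[iu]))
        others = [m for other, m in qualifying.items() if other != cid]
        pooled = np.vstack(others)
        inter = float(reduce(tanimoto_kernel(mat, pooled)))
        rows.append(ClassSimilarity(cid, n, intra, inter))

    ranked = sorted(rows, key=lambda r: (-r.difference, r.class_id))
    omitted = {r.class_id for r in ranked[:k_omit]}
    selected = sorted(cid for cid in qualifying if cid not in omitted)

    table = pd.DataFrame(
        {
            "class_id": [r.class_id for r in rows],
            "n_compounds": [r.n_compounds for r in rows],
            "intra": [r.intra for r in rows],
            "inter": [r.inter for r in rows],
            "difference": [r.difference for r in rows],
            "omitted": [r.class_id in omitted for r in rows],
        }
    )
    return selected, table
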