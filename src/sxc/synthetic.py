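"""Synthetic binary-fingerprint datasets with planted class structure.

Two compound classes are emulated by planting disjoint sets of
class-discriminative bits on top of a shared background bit distribution,
followed by independent bit-flip noise.  The planted sets are retained as
ground truth so that every downstream stage (training, attribution,
feature ranking, atom mapping) can be validated against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from sxc.seeding import derive_rng

__all__ = [
    "PotencyAnnotation",
    "CompoundRecord",
    "SyntheticPairSpec",
    "SyntheticDataset",
    "generate_class_pair",
    "generate_activity_records",
    "write_records_csv",
    "read_records_csv",
    "write_fingerprints",
    "read_fingerprints",
    "write_truth",
    "read_truth",
]

POTENCY_TYPES = ("Kd", "Ki", "IC50")

#: mass window (Da) a clean record must fall into
MASS_RANGE = (250.0, 1000.0)

#: required assay confidence score
REQUIRED_CONFIDENCE = 9

#: activity threshold on the negative decadic log molar potency (strict)
POTENCY_THRESHOLD = 5.0


class PotencyAnnotation(NamedTuple):
    """One potency measurement: type, pPot (-log10 molar) and assay confidence."""

    type: str
    ppot: float
    confidence: int


@dataclass
class CompoundRecord:
    """A single compound: fingerprint, class label and activity annotations."""

    compound_id: str
    class_label: str
    fingerprint: np.ndarray
    potency_annotations: list[PotencyAnnotation] = field(default_factory=list)
    molecular_mass: float = 400.0
    interference_flag: bool = False
    aggregator_flag: bool = False
    rule_violation_flag: bool = False
    atom_map: dict[int, frozenset[int]] | None = None
    planted_violation: str | None = None  # set by the generator, for tests

    def __post_init__(self) -> None:
        fp = np.asarray(self.fingerprint, dtype=np.int8)
        if not np.isin(fp, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0/1")
        self.fingerprint = fp
        if self.molecular_mass <= 0:
            raise ValueError("molecular mass must be positive")
        for ann in self.potency_annotations:
            if not np.isfinite(ann.ppot):
                raise ValueError("pPot must be finite")


@dataclass(frozen=True)
class SyntheticPairSpec:
    """Parameters of a two-class planted-bit fingerprint generator.

    ``planted_a`` / ``planted_b`` are disjoint sets of class-discriminative
    feature indices.  A planted bit of the compound's own class is on with
    probability ``p_planted_on``, a planted bit of the other class with
    ``p_cross_on``, all remaining bits with ``p_background``; every bit is
    then flipped independently with probability ``noise_rate``.
    """

    n_features: int = 256
    n_per_class: int = 100
    planted_a: frozenset[int] = frozenset()
    planted_b: frozenset[int] = frozenset()
    p_planted_on: float = 0.9
    p_cross_on: float = 0.05
    p_background: float = 0.1
    noise_rate: float = 0.0
    seed: int = 0
    class_a: str = "A"
    class_b: str = "B"

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_a", frozenset(self.planted_a))
        object.__setattr__(self, "planted_b", frozenset(self.planted_b))
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if self.planted_a & self.planted_b:
            raise ValueError("planted_a and planted_b must be disjoint")
        for s in (self.planted_a, self.planted_b):
            if any(i < 0 or i >= self.n_features for i in s):
                raise ValueError("planted indices must lie in [0, n_features)")
        for name in ("p_planted_on", "p_cross_on", "p_background", "noise_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.class_a == self.class_b:
            raise ValueError("class identifiers must differ")


@dataclass
class SyntheticDataset:
    """Generated records plus the planted ground truth and the generating spec."""

    records: list[CompoundRecord]
    truth: tuple[frozenset[int], frozenset[int]]
    spec: SyntheticPairSpec

    @property
    def class_ids(self) -> tuple[str, str]:
        return (self.spec.class_a, self.spec.class_b)

    def fingerprint_matrix(self) -> np.ndarray:
        return np.vstack([r.fingerprint for r in self.records])

    def labels(self) -> np.ndarray:
        return np.array([r.class_label for r in self.records])


def default_atom_map(fingerprint: np.ndarray) -> dict[int, frozenset[int]]:
    """Map each set bit ``i`` to the toy atom group ``{2i, 2i + 1}``.

    The toy molecule behind a length-``m`` fingerprint has ``2 m`` atoms, so
    every bit corresponds to a coherent two-atom substructure.
    """
    return {
        int(i): frozenset((2 * int(i), 2 * int(i) + 1))
        for i in np.flatnonzero(fingerprint)
    }


def _sample_fingerprints(
    rng: np.random.Generator, spec: SyntheticPairSpec, own: frozenset[int], other: frozenset[int]
) -> np.ndarray:
    p = np.full(spec.n_features, spec.p_background)
    p[sorted(own)] = spec.p_planted_on
    p[sorted(other)] = spec.p_cross_on
    bits = rng.random((spec.n_per_class, spec.n_features)) < p
    if spec.noise_rate > 0:
        flips = rng.random(bits.shape) < spec.noise_rate
        bits ^= flips
    else:
        rng.random(bits.shape)  # keep the stream position independent of noise_rate
    return bits.astype(np.int8)


def _clean_annotation(rng: np.random.Generator) -> PotencyAnnotation:
    # clean potency uniform in (5.5, 9.5), strictly above the activity threshold
    return PotencyAnnotation(
        type=str(rng.choice(POTENCY_TYPES)),
        ppot=float(rng.uniform(5.5, 9.5)),
        confidence=REQUIRED_CONFIDENCE,
    )


def generate_class_pair(spec: SyntheticPairSpec) -> SyntheticDataset:
    """Generate ``2 * n_per_class`` compound records for a planted class pair.

    Determinism contract: identical spec (including seed) yields bit-identical
    datasets.
    """
    rng_a = derive_rng(spec.seed, "class-pair", "fingerprints", spec.class_a)
    rng_b = derive_rng(spec.seed, "class-pair", "fingerprints", spec.class_b)
    rng_ann = derive_rng(spec.seed, "class-pair", "annotations")

    fps_a = _sample_fingerprints(rng_a, spec, spec.planted_a, spec.planted_b)
    fps_b = _sample_fingerprints(rng_b, spec, spec.planted_b, spec.planted_a)

    records: list[CompoundRecord] = []
    for label, fps in ((spec.class_a, fps_a), (spec.class_b, fps_b)):
        for i in range(spec.n_per_class):
            fp = fps[i]
            records.append(
                CompoundRecord(
                    compound_id=f"{label}-{i:05d}",
                    class_label=label,
                    fingerprint=fp,
                    potency_annotations=[_clean_annotation(rng_ann)],
                    molecular_mass=float(rng_ann.uniform(*MASS_RANGE)),
                    atom_map=default_atom_map(fp),
                )
            )
    return SyntheticDataset(records=records, truth=(spec.planted_a, spec.planted_b), spec=spec)


# Violation kinds cycled through by generate_activity_records.  Each entry
# builds a record breaking exactly the named curation rule.
_VIOLATION_KINDS = (
    "mass-range",
    "confidence",
    "low-potency",
    "inconsistent-potency",
    "no-potency",
    "interference",
    "aggregator",
    "rule-violation",
)


def generate_activity_records(
    spec: SyntheticPairSpec, n_clean: int, n_violating: int, seed: int
) -> list[CompoundRecord]:
    """Activity-record fixtures: ``n_clean`` records pass curation, ``n_violating`` do not.

    Each violating record breaks exactly one rule, recorded in
    ``planted_violation`` for test assertions.
    """
    if n_clean < 0 or n_violating < 0:
        raise ValueError("record counts must be non-negative")
    rng = derive_rng(seed, "activity-records")
    records: list[CompoundRecord] = []
    for i in range(n_clean):
        fp = (rng.random(spec.n_features) < spec.p_background).astype(np.int8)
        records.append(
            CompoundRecord(
                compound_id=f"clean-{i:05d}",
                class_label=spec.class_a,
                fingerprint=fp,
                potency_annotations=[_clean_annotation(rng)],
                molecular_mass=float(rng.uniform(*MASS_RANGE)),
            )
        )
    for i in range(n_violating):
        kind = _VIOLATION_KINDS[i % len(_VIOLATION_KINDS)]
        fp = (rng.random(spec.n_features) < spec.p_background).astype(np.int8)
        rec = CompoundRecord(
            compound_id=f"bad-{i:05d}",
            class_label=spec.class_b,
            fingerprint=fp,
            potency_annotations=[_clean_annotation(rng)],
            molecular_mass=float(rng.uniform(*MASS_RANGE)),
            planted_violation=kind,
        )
        if kind == "mass-range":
            rec.molecular_mass = float(rng.choice([120.0, 1500.0]))
        elif kind == "confidence":
            ann = rec.potency_annotations[0]
            rec.potency_annotations = [ann._replace(confidence=8)]
        elif kind == "low-potency":
            ann = rec.potency_annotations[0]
            # pPot <= 5: never counts as active
            rec.potency_annotations = [ann._replace(ppot=float(rng.uniform(3.0, 5.0)))]
        elif kind == "inconsistent-potency":
            ann = rec.potency_annotations[0]
            rec.potency_annotations = [
                ann,
                ann._replace(ppot=float(rng.uniform(3.0, 5.0))),
            ]
        elif kind == "no-potency":
            rec.potency_annotations = []
        elif kind == "interference":
            rec.interference_flag = True
        elif kind == "aggregator":
            rec.aggregator_flag = True
        elif kind == "rule-violation":
            rec.rule_violation_flag = True
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "compound_id",
    "class_label",
    "molecular_mass",
    "potency_annotations",
    "interference_flag",
    "aggregator_flag",
    "rule_violation_flag",
    "fingerprint",
]


def write_records_csv(records: Sequence[CompoundRecord], path: str | Path) -> None:
    """Records as CSV; fingerprints serialized as 0/1 strings, annotations as JSON."""
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "class_label": r.class_label,
                "molecular_mass": r.molecular_mass,
                "potency_annotations": json.dumps(
                    [[a.type, a.ppot, a.confidence] for a in r.potency_annotations]
                ),
                "interference_flag": r.interference_flag,
                "aggregator_flag": r.aggregator_flag,
                "rule_violation_flag": r.rule_violation_flag,
                "fingerprint": "".join(map(str, r.fingerprint.tolist())),
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[CompoundRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        fp = np.frombuffer(str(row.fingerprint).encode(), dtype=np.uint8) - ord("0")
        records.append(
            CompoundRecord(
                compound_id=str(row.compound_id),
                class_label=str(row.class_label),
                fingerprint=fp.astype(np.int8),
                potency_annotations=[
                    PotencyAnnotation(t, float(p), int(c))
                    for t, p, c in json.loads(row.potency_annotations)
                ],
                molecular_mass=float(row.molecular_mass),
                interference_flag=bool(row.interference_flag),
                aggregator_flag=bool(row.aggregator_flag),
                rule_violation_flag=bool(row.rule_violation_flag),
            )
        )
    return records


def write_fingerprints(matrix: np.ndarray, path: str | Path) -> None:
    """Fingerprint matrix as MatrixMarket (``.mtx``) or CSV, by extension."""
    path = Path(path)
    if path.suffix == ".mtx":
        mmwrite(str(path), csr_matrix(np.asarray(matrix)))
    else:
        pd.DataFrame(np.asarray(matrix, dtype=int)).to_csv(path, index=False, header=False)


def read_fingerprints(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".mtx":
        return np.asarray(mmread(str(path)).todense(), dtype=np.int8)
    return pd.read_csv(path, header=None).to_numpy(dtype=np.int8)


def write_truth(dataset: SyntheticDataset, path: str | Path) -> None:
    payload = {
        "class_a": dataset.spec.class_a,
        "class_b": dataset.spec.class_b,
        "planted_a": sorted(dataset.truth[0]),
        "planted_b": sorted(dataset.truth[1]),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_truth(path: str | Path) -> tuple[frozenset[int], frozenset[int]]:
    payload = json.loads(Path(path).read_text())
    return frozenset(payload["planted_a"]), frozenset(payload["planted_b"])
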