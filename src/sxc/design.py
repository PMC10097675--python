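"""Experimental design: job enumeration and balanced trial splits.

One job per (unordered class pair, training-set size, trial, algorithm).
Within a trial a single balanced test set is drawn first and reused across
all training-set sizes, so per-compound prediction patterns are
well-defined; train/validation sets of each size are then drawn
independently from the remaining pool.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sxc.seeding import derive_rng
from sxc.synthetic import SyntheticDataset

__all__ = [
    "DEFAULT_SIZE_SCHEDULE",
    "DesignSpec",
    "TrialSplit",
    "enumerate_jobs",
    "validation_per_class",
    "make_trial_splits",
]

#: per-class training counts; endpoints 5 and 720 with 125/class included
DEFAULT_SIZE_SCHEDULE = (5, 10, 25, 50, 75, 100, 125, 250, 375, 500, 625, 720)


def validation_per_class(size_per_class: int, validation_fraction: float = 0.2) -> int:
    """Balanced per-class validation count for a balanced two-class training set.

    Total validation size is the fraction of the total training size rounded
    half-up, then forced to an even split with at least one compound per
    class (5/class training -> 2-compound validation set).
    """
    total = int(math.floor(validation_fraction * 2 * size_per_class + 0.5))
    return max(1, -(-total // 2))


@dataclass(frozen=True)
class DesignSpec:
    class_ids: tuple[str, ...] = ("1", "2", "3", "4", "5", "6", "7")
    size_schedule: tuple[int, ...] = DEFAULT_SIZE_SCHEDULE
    n_trials: int = 10
    test_per_class: int = 100
    validation_fraction: float = 0.2
    algorithms: tuple[str, ...] = ("RF", "SVM")
    master_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_ids", tuple(self.class_ids))
        object.__setattr__(self, "size_schedule", tuple(self.size_schedule))
        object.__setattr__(self, "algorithms", tuple(self.algorithms))
        if len(set(self.class_ids)) != len(self.class_ids):
            raise ValueError("duplicate class ids")
        if len(self.class_ids) < 2:
            raise ValueError("need at least two classes")
        if any(b <= a for a, b in zip(self.size_schedule, self.size_schedule[1:])):
            raise ValueError("size schedule must be strictly increasing")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if not set(self.algorithms) <= {"RF", "SVM"} or not self.algorithms:
            raise ValueError("algorithms must be a non-empty subset of {RF, SVM}")
        if self.n_trials < 1 or self.test_per_class < 1:
            raise ValueError("n_trials and test_per_class must be positive")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.class_ids, 2))

    def min_pool_per_class(self) -> int:
        """Smallest per-class pool compatible with the splits."""
        need = max(
            s + validation_per_class(s, self.validation_fraction)
            for s in self.size_schedule
        )
        return need + self.test_per_class


def enumerate_jobs(design: DesignSpec) -> pd.DataFrame:
    """Full job manifest with deterministic per-job seeds.

    The split seed depends only on (pair, trial) so RF and SVM of the same
    job family train on identical data sets; the search seed additionally
    depends on size and algorithm.
    """
    rows = []
    for p_idx, (ca, cb) in enumerate(design.pairs):
        for s_idx, size in enumerate(design.size_schedule):
            for trial in range(design.n_trials):
                split_seed = int(
                    derive_rng(design.master_seed, "split-seed", p_idx, trial).integers(2**31 - 1)
                )
                for algorithm in design.algorithms:
                    search_seed = int(
                        derive_rng(
                            design.master_seed, "search-seed", p_idx, s_idx, trial, algorithm
                        ).integers(2**31 - 1)
                    )
                    rows.append(
                        {
                            "job_id": f"{ca}-vs-{cb}_size{size}_trial{trial}_{algorithm}",
                            "class_a": ca,
                            "class_b": cb,
                            "pair_index": p_idx,
                            "size_per_class": size,
                            "size_index": s_idx,
                            "trial": trial,
                            "algorithm": algorithm,
                            "split_seed": split_seed,
                            "search_seed": search_seed,
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class TrialSplit:
    """Balanced, disjoint index sets for one trial of one class pair.

    Indices refer to rows of the pool the split was made from.  ``test``
    is shared across all sizes; ``by_size`` maps per-class training size to
    (train indices, validation indices).
    """

    pair: tuple[str, str]
    trial_index: int
    test: np.ndarray
    by_size: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def validate(self) -> None:
        test = set(self.test.tolist())
        for size, (train, val) in self.by_size.items():
            tr, va = set(train.tolist()), set(val.tolist())
            if tr & va or (tr | va) & test:
                raise AssertionError(f"split overlap at size {size}")


def _per_class_indices(pool: SyntheticDataset, class_id: str) -> np.ndarray:
    return np.array(
        [i for i, r in enumerate(pool.records) if r.class_label == class_id], dtype=np.int64
    )


def make_trial_splits(
    pool: SyntheticDataset,
    design: DesignSpec,
    pair: tuple[str, str],
    trial_index: int,
) -> TrialSplit:
    """Draw the test set, then per-size balanced train/validation sets.

    Training sets of different sizes are sampled independently (not nested)
    from the pool minus the test set.
    """
    ca, cb = pair
    rng = derive_rng(design.master_seed, "trial-split", ca, cb, trial_index)

    idx_a = _per_class_indices(pool, ca)
    idx_b = _per_class_indices(pool, cb)
    need = design.min_pool_per_class()
    for cid, idx in ((ca, idx_a), (cb, idx_b)):
        if len(idx) < need:
            raise ValueError(
                f"pool class {cid!r} has {len(idx)} compounds; "
                f"the design needs at least {need} per class"
            )

    test_a = rng.choice(idx_a, size=design.test_per_class, replace=False)
    test_b = rng.choice(idx_b, size=design.test_per_class, replace=False)
    rest_a = np.setdiff1d(idx_a, test_a)
    rest_b = np.setdiff1d(idx_b, test_b)

    split = TrialSplit(pair=(ca, cb), trial_index=trial_index,
                       test=np.sort(np.concatenate([test_a, test_b])))
    for size in design.size_schedule:
        vpc = validation_per_class(size, design.validation_fraction)
        picked_a = rng.choice(rest_a, size=size + vpc, replace=False)
        picked_b = rng.choice(rest_b, size=size + vpc, replace=False)
        train = np.sort(np.concatenate([picked_a[:size], picked_b[:size]]))
        val = np.sort(np.concatenate([picked_a[size:], picked_b[size:]]))
        split.by_size[size] = (train, val)
    split.validate()
    return split
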