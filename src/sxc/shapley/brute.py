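"""Brute-force Shapley enumeration — the small-m exact reference.

phi_j = sum over S subseteq F \\ {j} of |S|! (m - |S| - 1)! / m! *
        (v(S + {j}) - v(S))

Exponential in m; refuses m above the enumeration bound.  Every efficient
engine in this package is validated against this function.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = ["brute_force_shapley", "ENUMERATION_BOUND"]

ENUMERATION_BOUND = 15


def brute_force_shapley(
    value_function: Callable[[tuple[int, ...]], float],
    m: int,
    max_m: int = ENUMERATION_BOUND,
) -> np.ndarray:
    """Exact Shapley values of an m-player coalition game by full enumeration.

    ``value_function`` receives a sorted tuple of player indices.  Raises for
    ``m > max_m``; use the closed-form engines for larger games.
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    if m > max_m:
        raise ValueError(
            f"m={m} exceeds the enumeration bound {max_m}; "
            "use the closed-form engines for large games"
        )
    if m == 0:
        return np.zeros(0)

    n_masks = 1 << m
    v = np.empty(n_masks, dtype=np.float64)
    members: list[tuple[int, ...]] = [()] * n_masks
    for mask in range(n_masks):
        subset = tuple(j for j in range(m) if mask >> j & 1)
        members[mask] = subset
        v[mask] = value_function(subset)

    fact = [math.factorial(k) for k in range(m + 1)]
    # weight by coalition size |S| (j excluded)
    weight = np.array([fact[s] * fact[m - s - 1] / fact[m] for s in range(m)])

    phi = np.zeros(m)
    popcount = np.array([len(members[mask]) for mask in range(n_masks)])
    for j in range(m):
        bit = 1 << j
        without = np.array([mask for mask in range(n_masks) if not mask & bit])
        phi[j] = float(np.sum(weight[popcount[without]] * (v[without | bit] - v[without])))
    return phi


def additive_game(weights: Sequence[float]) -> Callable[[tuple[int, ...]], float]:
    """v(S) = sum of weights over S; Shapley values equal the weights."""
    w = np.asarray(weights, dtype=np.float64)

    def v(subset: tuple[int, ...]) -> float:
        return float(w[list(subset)].sum()) if subset else 0.0

    return v
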