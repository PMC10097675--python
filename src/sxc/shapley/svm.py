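"""Exact Shapley values for Tanimoto-kernel SVM decision functions.

Per support vector ``s``, the coalition game over fingerprint positions is
the *restricted-kernel game*: for a coalition S, the Tanimoto similarity of
``x`` and ``s`` is computed only over the positions in S (0 when the
restricted union is empty).  Relative to the explained compound, positions
fall into at most four equivalence classes by ``(x_j, s_j)``:

* ``(1, 1)`` — shared bits.  The game value depends on the coalition only
  through the number of shared bits ``i`` and mismatched bits ``u`` it
  contains: ``v = i / (i + u)``.
* ``(1, 0)`` and ``(0, 1)`` — mismatches.  Symmetric players: equal values.
* ``(0, 0)`` — dummies with value exactly 0.

Because dummy players do not alter the values of others, the Shapley value
of a relevant player is computed over the ``d = n11 + n10 + n01`` relevant
players only.  The per-class closed forms below sum the marginal
contribution over coalition compositions ``(i, u)`` weighted by
``C(.) * i! (d - 1 - i - u)! / d!``; they are exact rationals for moderate
``d`` and log-space sums beyond.  Per-support-vector values combine
linearly with the dual coefficients; the intercept is the base value.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy.special import gammaln

from sxc.shapley.explanation import ShapleyExplanation

__all__ = [
    "restricted_tanimoto_game",
    "pair_class_shapley_values",
    "tanimoto_decision_shapley",
    "svm_tanimoto_shapley",
]

# up to this many relevant players the class values are computed in exact
# rational arithmetic; beyond, in log space (errors ~1e-14 relative)
_EXACT_LIMIT = 120


def restricted_tanimoto_game(x: np.ndarray, s: np.ndarray) -> Callable[[tuple[int, ...]], float]:
    """Coalition game v(S) = Tanimoto(x, s) restricted to positions in S.

    v(S) = c_S / (a_S + b_S - c_S) over coalition positions; 0 when the
    denominator is 0 (in particular v(empty) = 0).
    """
    x = np.asarray(x, dtype=np.int64)
    s = np.asarray(s, dtype=np.int64)
    if x.shape != s.shape:
        raise ValueError("fingerprint length mismatch")

    def v(subset: tuple[int, ...]) -> float:
        if not subset:
            return 0.0
        idx = list(subset)
        xs = x[idx]
        ss = s[idx]
        c = int((xs & ss).sum())
        union = int(xs.sum() + ss.sum()) - c
        return c / union if union else 0.0

    return v


@lru_cache(maxsize=None)
def pair_class_shapley_values(n11: int, n_mismatch: int) -> tuple[float, float]:
    """Shapley value of one shared bit and one mismatched bit of the
    restricted-kernel game with ``n11`` shared and ``n_mismatch`` mismatched
    positions.  Dummy (0, 0) positions have value 0 and are not returned.

    Efficiency: ``n11 * phi_shared + n_mismatch * phi_mismatch ==
    n11 / (n11 + n_mismatch)`` (the full Tanimoto similarity).
    """
    d = n11 + n_mismatch
    if d == 0:
        return 0.0, 0.0
    if d <= _EXACT_LIMIT:
        return _values_exact(n11, n_mismatch)
    return _values_logspace(n11, n_mismatch)


def _values_exact(n11: int, n_mismatch: int) -> tuple[float, float]:
    d = n11 + n_mismatch
    fact = math.factorial
    comb = math.comb

    phi_shared = Fraction(0)
    for i in range(n11):  # shared bits already in S (others than the player)
        for u in range(n_mismatch + 1):
            w = Fraction(fact(i + u) * fact(d - 1 - i - u), fact(d))
            cnt = comb(n11 - 1, i) * comb(n_mismatch, u)
            v1 = Fraction(i + 1, i + 1 + u)
            v0 = Fraction(i, i + u) if i + u else Fraction(0)
            phi_shared += cnt * w * (v1 - v0)

    phi_mismatch = Fraction(0)
    for i in range(n11 + 1):
        for u in range(n_mismatch):
            w = Fraction(fact(i + u) * fact(d - 1 - i - u), fact(d))
            cnt = comb(n11, i) * comb(n_mismatch - 1, u)
            v1 = Fraction(i, i + u + 1)
            v0 = Fraction(i, i + u) if i + u else Fraction(0)
            phi_mismatch += cnt * w * (v1 - v0)

    return float(phi_shared), float(phi_mismatch)


def _values_logspace(n11: int, n_mismatch: int) -> tuple[float, float]:
    d = n11 + n_mismatch

    def log_w(s):  # log of s! (d-1-s)! / d!
        return gammaln(s + 1) + gammaln(d - s) - gammaln(d + 1)

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    phi_shared = 0.0
    if n11 > 0:
        i = np.arange(n11)[:, None].astype(float)
        u = np.arange(n_mismatch + 1)[None, :].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            v0 = np.where(i + u > 0, i / np.maximum(i + u, 1), 0.0)
        marg = (i + 1) / (i + 1 + u) - v0  # >= 0
        logs = log_comb(n11 - 1, i) + log_comb(n_mismatch, u) + log_w(i + u)
        phi_shared = float(np.sum(np.exp(logs) * marg))

    phi_mismatch = 0.0
    if n_mismatch > 0:
        i = np.arange(n11 + 1)[:, None].astype(float)
        u = np.arange(n_mismatch)[None, :].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            v0 = np.where(i + u > 0, i / np.maximum(i + u, 1), 0.0)
        marg = i / (i + u + 1) - v0  # <= 0
        logs = log_comb(n11, i) + log_comb(n_mismatch - 1, u) + log_w(i + u)
        phi_mismatch = float(np.sum(np.exp(logs) * marg))

    return phi_shared, phi_mismatch


def tanimoto_decision_shapley(
    x: np.ndarray,
    support_vectors: np.ndarray,
    dual_coefs: np.ndarray,
    intercept: float,
) -> tuple[np.ndarray, float, float]:
    """Shapley values of f(x) = sum_i w_i * Tanimoto(x, s_i) + b.

    Returns ``(values, base_value, model_output)`` with
    ``base_value + values.sum() == model_output`` (local accuracy).
    """
    x = np.asarray(x, dtype=np.int8)
    sv = np.atleast_2d(np.asarray(support_vectors, dtype=np.int8))
    w = np.asarray(dual_coefs, dtype=np.float64).ravel()
    if not np.isin(x, (0, 1)).all() or not np.isin(sv, (0, 1)).all():
        raise ValueError("fingerprints must be binary")
    if sv.shape[0] != w.shape[0]:
        raise ValueError("one dual coefficient per support vector required")
    if sv.shape[1] != x.shape[0]:
        raise ValueError("fingerprint length mismatch")

    xf = x.astype(np.float64)
    svf = sv.astype(np.float64)
    n11 = (svf @ xf).astype(np.int64)
    n_mismatch = (np.abs(svf - xf[None, :]).sum(axis=1)).astype(np.int64)

    coef_shared = np.empty(len(w))
    coef_mismatch = np.empty(len(w))
    for i, (a, b) in enumerate(zip(n11.tolist(), n_mismatch.tolist())):
        phi_s, phi_m = pair_class_shapley_values(a, b)
        coef_shared[i] = w[i] * phi_s
        coef_mismatch[i] = w[i] * phi_m

    shared_mask = svf * xf[None, :]                    # (x_j, s_j) = (1, 1)
    mismatch_mask = np.abs(svf - xf[None, :])          # (1, 0) or (0, 1)
    values = coef_shared @ shared_mask + coef_mismatch @ mismatch_mask

    denom = n11 + n_mismatch
    kernel = np.where(denom > 0, n11 / np.maximum(denom, 1), 0.0)
    output = float(w @ kernel + intercept)
    return values, float(intercept), output


def svm_tanimoto_shapley(model, x: np.ndarray, compound_id: str = "") -> ShapleyExplanation:
    """Explain a Tanimoto-SVM decision for one compound.

    The raw decision function is positive for the alphabetically second
    class; the returned explanation is oriented to the *first* class (the
    shared reference orientation of the package), i.e. the decision value
    and all attributions are negated.
    """
    if getattr(model, "algorithm", None) != "SVM":
        raise ValueError("svm_tanimoto_shapley requires a Tanimoto-SVM TrainedModel")
    est = model.estimator
    sv = model.x_train[est.support_]
    values, base, output = tanimoto_decision_shapley(
        x, sv, est.dual_coef_[0], float(est.intercept_[0])
    )
    return ShapleyExplanation(
        compound_id=compound_id,
        values=-values,
        base_value=-base,
        model_output=-output,
        orientation=model.classes[0],
        kind="decision",
    )
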