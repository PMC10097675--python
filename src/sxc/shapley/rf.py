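"""Exact interventional Shapley values for tree-ensemble probabilities.

The coalition game for compound ``x`` with background set Z is

    v(S) = mean over z in Z of p(composite(x on S, z off S))

where ``p`` is the ensemble probability of the reference class.  For a
single tree, leaf and background row, the composite reaches the leaf iff a
set P of path features takes x's side (these must be *in* the coalition)
and a set N takes z's side (these must be *out*); all other features are
irrelevant.  The Shapley value of such a conjunction-of-literals game has
the closed form

    phi_j = +leaf / (|P| * C(|P| + |N|, |P|))   for j in P
    phi_j = -leaf / (|N| * C(|P| + |N|, |N|))   for j in N

which is summed over leaves, trees and background rows.  The computation is
exact (validated against brute-force enumeration) and vectorized over
explained compounds and background rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from sxc.shapley.explanation import ShapleyExplanation

__all__ = ["RFExplainer", "rf_tree_shapley", "interventional_game"]


@dataclass
class _Leaf:
    features: np.ndarray   # distinct feature ids on the path, shape (k,)
    lower: np.ndarray      # open lower bounds per feature
    upper: np.ndarray      # closed upper bounds per feature
    prob: float            # reference-class probability at the leaf
    sat_bg: np.ndarray     # (n_background, k) path satisfaction of each row


def _leaf_paths(tree, class_index: int):
    """Yield (features, lower, upper, prob) for every leaf of a fitted tree."""
    feature = tree.feature
    threshold = tree.threshold
    left = tree.children_left
    right = tree.children_right
    value = tree.value

    stack = [(0, {})]  # node, {feature: (lower, upper)}
    while stack:
        node, bounds = stack.pop()
        if left[node] == -1:  # leaf
            counts = value[node].ravel()
            prob = float(counts[class_index] / counts.sum())
            feats = np.fromiter(bounds.keys(), dtype=np.int64, count=len(bounds))
            lo = np.array([bounds[f][0] for f in feats], dtype=np.float64)
            hi = np.array([bounds[f][1] for f in feats], dtype=np.float64)
            yield feats, lo, hi, prob
            continue
        f = int(feature[node])
        t = float(threshold[node])
        lo, hi = bounds.get(f, (-np.inf, np.inf))
        # left branch: value <= t ; right branch: value > t
        if t < hi:
            b = dict(bounds)
            b[f] = (lo, min(hi, t))
            stack.append((int(left[node]), b))
        if t > lo:
            b = dict(bounds)
            b[f] = (max(lo, t), hi)
            stack.append((int(right[node]), b))


class RFExplainer:
    """Preprocess a fitted forest + background once, then explain batches.

    ``class_index`` selects the probability column being explained (default
    0: the alphabetically first class, the package's reference orientation).
    """

    def __init__(self, forest, background: np.ndarray, class_index: int = 0):
        background = np.asarray(background, dtype=np.float64)
        if background.ndim != 2 or background.shape[0] == 0:
            raise ValueError("background must be a non-empty 2-D matrix")
        self.forest = forest
        self.background = background
        self.class_index = int(class_index)
        self.n_features = background.shape[1]
        self.n_background = background.shape[0]

        col = self.class_index
        self.base_value = float(forest.predict_proba(background)[:, col].mean())

        self._leaves: list[_Leaf] = []
        max_k = 1
        for est in forest.estimators_:
            for feats, lo, hi, prob in _leaf_paths(est.tree_, col):
                sat_bg = (background[:, feats] > lo) & (background[:, feats] <= hi)
                self._leaves.append(_Leaf(feats, lo, hi, prob, sat_bg))
                max_k = max(max_k, len(feats) + 1)
        self.n_trees = len(forest.estimators_)

        # weight lookup tables: w_in[a, b] = 1 / (a * C(a+b, a)), a >= 1
        size = max_k + 1
        self._w_in = np.zeros((size, size))
        self._w_out = np.zeros((size, size))
        for a in range(size):
            for b in range(size):
                if a >= 1 and a + b < size:
                    self._w_in[a, b] = 1.0 / (a * math.comb(a + b, a))
                if b >= 1 and a + b < size:
                    self._w_out[a, b] = 1.0 / (b * math.comb(a + b, b))

    def shapley_values(self, x_batch: np.ndarray) -> np.ndarray:
        """Exact interventional Shapley values, one row per explained compound."""
        x_batch = np.atleast_2d(np.asarray(x_batch, dtype=np.float64))
        if x_batch.shape[1] != self.n_features:
            raise ValueError("feature dimension mismatch")
        n = x_batch.shape[0]
        phi = np.zeros((n, self.n_features))
        norm = 1.0 / (self.n_background * self.n_trees)

        for leaf in self._leaves:
            k = len(leaf.features)
            if k == 0:
                continue  # leaf reached unconditionally: no marginals
            sat_x = (x_batch[:, leaf.features] > leaf.lower) & (
                x_batch[:, leaf.features] <= leaf.upper
            )  # (n, k)
            sat_z = leaf.sat_bg  # (nb, k)
            p_in = sat_x[:, None, :] & ~sat_z[None, :, :]    # feature must be in S
            p_out = ~sat_x[:, None, :] & sat_z[None, :, :]   # feature must be out
            dead = ~sat_x[:, None, :] & ~sat_z[None, :, :]
            reach = ~dead.any(axis=2)                        # (n, nb)
            if not reach.any():
                continue
            p_in &= reach[:, :, None]
            p_out &= reach[:, :, None]
            a = p_in.sum(axis=2)
            b = p_out.sum(axis=2)
            w_in = self._w_in[a, b]
            w_out = self._w_out[a, b]
            contrib = (
                (p_in * w_in[:, :, None]).sum(axis=1)
                - (p_out * w_out[:, :, None]).sum(axis=1)
            ) * (leaf.prob * norm)
            phi[:, leaf.features] += contrib  # features are distinct within a leaf
        return phi

    def explain_batch(
        self, x_batch: np.ndarray, compound_ids: Sequence[str], orientation: str
    ) -> list[ShapleyExplanation]:
        x_batch = np.atleast_2d(np.asarray(x_batch))
        col = self.class_index
        outputs = self.forest.predict_proba(x_batch)[:, col]
        phi = self.shapley_values(x_batch)
        return [
            ShapleyExplanation(
                compound_id=str(cid),
                values=phi[i],
                base_value=self.base_value,
                model_output=float(outputs[i]),
                orientation=orientation,
                kind="probability",
            )
            for i, cid in enumerate(compound_ids)
        ]


def rf_tree_shapley(
    model, x: np.ndarray, background: np.ndarray | None = None, compound_id: str = ""
) -> ShapleyExplanation:
    """Explain one RF prediction; default background is the training set.

    The explained output is the probability of the alphabetically first
    class (the package's reference orientation).
    """
    if getattr(model, "algorithm", None) != "RF":
        raise ValueError("rf_tree_shapley requires an RF TrainedModel")
    bg = model.x_train if background is None else np.asarray(background)
    if bg.size == 0:
        raise ValueError("background must be non-empty")
    class_index = list(model.estimator.classes_).index(0)
    explainer = RFExplainer(model.estimator, bg, class_index=class_index)
    return explainer.explain_batch(
        np.atleast_2d(x), [compound_id], orientation=model.classes[0]
    )[0]


def interventional_game(
    forest, x: np.ndarray, background: np.ndarray, class_index: int = 0
) -> Callable[[tuple[int, ...]], float]:
    """The oracle game: v(S) = mean background probability of the composite.

    Used by the brute-force validation suite; intentionally independent of
    the traversal algorithm above.
    """
    x = np.asarray(x, dtype=np.float64)
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    col = class_index

    def v(subset: tuple[int, ...]) -> float:
        composite = background.copy()
        if subset:
            idx = list(subset)
            composite[:, idx] = x[idx]
        return float(forest.predict_proba(composite)[:, col].mean())

    return v
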