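"""Projection of present-feature Shapley values onto atoms.

Each present fingerprint bit carries a set of atom indices (the
substructure it encodes).  The bit's full Shapley value is assigned to
every atom it covers (an even-split mode divides it instead), and atoms
are binned into a tri-level color code: cyan (opposing, < -tau), white
(neutral, within tau) and magenta (supporting, > tau).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from sxc.shapley.explanation import ShapleyExplanation

__all__ = ["map_feature_values_to_atoms", "color_bins"]


def map_feature_values_to_atoms(
    expl: ShapleyExplanation,
    x: np.ndarray,
    atom_map: Mapping[int, frozenset[int] | set[int]],
    n_atoms: int | None = None,
    split: bool = False,
) -> np.ndarray:
    """Per-atom value vector from the present features of one explanation.

    Only present features (``x_j == 1``) are mapped; each must have an atom
    assignment.  With ``split=True`` a feature's value is divided evenly
    among its atoms instead of fully assigned to each.
    """
    x = np.asarray(x)
    if x.shape[0] != expl.values.shape[0]:
        raise ValueError("fingerprint / explanation length mismatch")
    present = [int(j) for j in np.flatnonzero(x == 1)]
    missing = [j for j in present if j not in atom_map or not atom_map[j]]
    if missing:
        raise ValueError(f"present features without atom assignment: {missing}")
    if n_atoms is None:
        n_atoms = 1 + max((max(atom_map[j]) for j in present), default=-1)
    atom_values = np.zeros(n_atoms)
    for j in present:
        atoms = sorted(atom_map[j])
        value = float(expl.values[j])
        if split:
            value /= len(atoms)
        for a in atoms:
            atom_values[a] += value
    return atom_values


def color_bins(atom_values: np.ndarray, tau: float = 1e-6) -> list[str]:
    """Tri-level color code per atom: cyan / white / magenta."""
    bins = []
    for v in np.asarray(atom_values, dtype=np.float64):
        if v < -tau:
            bins.append("cyan")
        elif v > tau:
            bins.append("magenta")
        else:
            bins.append("white")
    return bins
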