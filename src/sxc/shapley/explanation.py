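"""Explanation container and sign orientation."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ShapleyExplanation", "orient_explanation"]


@dataclass
class ShapleyExplanation:
    """Per-feature attribution of one model output for one compound.

    ``kind`` is ``"probability"`` (RF: the explained output is a class
    probability) or ``"decision"`` (SVM: signed distance to the separating
    hyperplane).  ``orientation`` names the class a positive value supports.
    Local accuracy: ``base_value + values.sum() == model_output``.
    """

    compound_id: str
    values: np.ndarray
    base_value: float
    model_output: float
    orientation: str
    kind: str  # "probability" | "decision"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.kind not in ("probability", "decision"):
            raise ValueError(f"unknown explanation kind: {self.kind!r}")

    def local_accuracy_error(self) -> float:
        return float(abs(self.base_value + self.values.sum() - self.model_output))


def orient_explanation(
    expl: ShapleyExplanation, true_class: str, classes: tuple[str, str]
) -> ShapleyExplanation:
    """Flip the sign convention so positive always supports ``true_class``.

    Probability explanations map output p to 1 - p (binary complement);
    decision explanations map distance d to -d.
    """
    if true_class not in classes:
        raise ValueError(f"unknown class id: {true_class!r}")
    if true_class == expl.orientation:
        return expl
    other = classes[0] if true_class == classes[1] else classes[1]
    if expl.orientation != other:
        raise ValueError("explanation orientation does not match the class pair")
    if expl.kind == "probability":
        return replace(
            expl,
            values=-expl.values,
            base_value=1.0 - expl.base_value,
            model_output=1.0 - expl.model_output,
            orientation=true_class,
        )
    return replace(
        expl,
        values=-expl.values,
        base_value=-expl.base_value,
        model_output=-expl.model_output,
        orientation=true_class,
    )
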