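"""Three-state accuracy metrics: Q3 and the confusion matrix."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .alphabet import STATES, StructureString


def q3(pred: StructureString, truth: StructureString) -> float:
    """Percentage of residues whose predicted state matches the reference."""
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: prediction {len(pred)} vs truth {len(truth)}")
    match = sum(a == b for a, b in zip(pred.states, truth.states))
    return 100.0 * match / len(truth)


def confusion_matrix(pred: StructureString, truth: StructureString) -> np.ndarray:
    """3x3 counts[true][pred] in state order H, E, C."""
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: prediction {len(pred)} vs truth {len(truth)}")
    return _sk_confusion(list(truth.states), list(pred.states), labels=list(STATES))


def pooled_q3(pairs: list[tuple[StructureString, StructureString]]) -> float:
    """Residue-weighted Q3 pooled over many (pred, truth) pairs."""
    total = sum(len(t) for _, t in pairs)
    match = sum(sum(a == b for a, b in zip(p.states, t.states)) for p, t in pairs)
    if total == 0:
        raise ValueError("no residues to evaluate")
    return 100.0 * match / total


def pooled_confusion(pairs: list[tuple[StructureString, StructureString]]) -> np.ndarray:
    """3x3 confusion counts pooled over many (pred, truth) pairs."""
    out = np.zeros((3, 3), dtype=np.int64)
    for p, t in pairs:
        out += confusion_matrix(p, t)
    return out
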