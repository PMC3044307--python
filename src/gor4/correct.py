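"""The two scanning correction passes applied after preliminary prediction.

Pass 1 dissolves helix runs too short to be physical (an alpha-helix turn
spans about four residues): each residue of a short maximal H-run is
reassigned to whichever of E or C has the higher predicted probability
there (ties to C). Pass 2 removes strand runs shorter than the minimum
(default two residues), turning them into coil. Pass 1 never creates an H
and pass 2 never creates an H or E, so the composite is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .alphabet import StructureString
from .io import _prob_matrix


@dataclass(frozen=True)
class CorrectionConfig:
    """Minimum physically plausible run lengths for helix and strand."""

    min_helix_run: int = 4
    min_strand_run: int = 2

    def __post_init__(self) -> None:
        if self.min_helix_run < 1 or self.min_strand_run < 1:
            raise ValueError("minimum run lengths must be >= 1")


def _runs(states: str) -> Iterator[tuple[int, int, str]]:
    """Maximal runs as (start, end_exclusive, state)."""
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            yield start, i, states[start]
            start = i


def correction_pass1(
    states: StructureString, probs, cfg: CorrectionConfig = CorrectionConfig()
) -> StructureString:
    """Dissolve maximal H-runs shorter than min_helix_run.

    Each residue of a dissolved run becomes E or C, whichever has the
    higher probability at that residue (tie -> C). E and C residues are
    untouched.
    """
    mat = _prob_matrix(probs)
    if mat.shape[0] != len(states):
        raise ValueError(
            f"length mismatch: {len(states)} states vs {mat.shape[0]} probability rows"
        )
    out = list(states.states)
    for start, end, state in _runs(states.states):
        if state == "H" and end - start < cfg.min_helix_run:
            for i in range(start, end):
                out[i] = "E" if mat[i, 1] > mat[i, 2] else "C"
    return StructureString("".join(out))


def correction_pass2(
    states: StructureString, cfg: CorrectionConfig = CorrectionConfig()
) -> StructureString:
    """Reassign maximal E-runs shorter than min_strand_run to coil."""
    out = list(states.states)
    for start, end, state in _runs(states.states):
        if state == "E" and end - start < cfg.min_strand_run:
            for i in range(start, end):
                out[i] = "C"
    return StructureString("".join(out))


def apply_corrections(
    states: StructureString, probs, cfg: CorrectionConfig = CorrectionConfig()
) -> StructureString:
    """Both passes in order: helix smoothing, then strand smoothing.

    Pass 2 vets any E residues introduced by pass 1, so the composite is
    idempotent.
    """
    return correction_pass2(correction_pass1(states, probs, cfg), cfg)
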