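"""Residue alphabet, 5-bit encoding, and the core sequence/structure types.

The predictor works on a 21-symbol alphabet: the 20 canonical amino acids in
alphabetical one-letter order (A=0 .. Y=19) plus a boundary/unknown symbol
``X`` with code 20. Every code fits in 5 bits, matching a compact binary
sequence encoding. ``X`` doubles as the padding symbol read at window
positions that fall outside the sequence, and as the sink for non-canonical
residue letters (B, J, O, U, Z, X and ambiguity codes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical amino acids, alphabetical by one-letter code.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
#: Boundary / unknown symbol.
UNKNOWN_SYMBOL = "X"
#: Full 21-symbol alphabet; index == residue code.
SYMBOLS = AA_ORDER + UNKNOWN_SYMBOL
#: Code of the unknown/padding symbol.
UNKNOWN_CODE = 20
#: Alphabet size.
ALPHABET_SIZE = 21

#: Three-state secondary-structure alphabet, in fixed priority order.
STATES = "HEC"
N_STATES = 3

_CODE_OF = {aa: i for i, aa in enumerate(AA_ORDER)}
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}

assert len(SYMBOLS) == ALPHABET_SIZE and max(range(ALPHABET_SIZE)) <= 31


def code_of(symbol: str) -> int:
    """Residue code of a single uppercase letter (non-canonical -> 20)."""
    return _CODE_OF.get(symbol, UNKNOWN_CODE)


def state_index(state: str) -> int:
    """Index of a structure state: H -> 0, E -> 1, C -> 2."""
    try:
        return _STATE_INDEX[state]
    except KeyError:
        raise ValueError(f"invalid state {state!r}: expected one of H, E, C") from None


@dataclass
class ProteinSequence:
    """An encoded amino-acid sequence.

    ``codes`` holds one integer in 0..20 per residue; ``id`` is the record
    identifier carried through from the input file.
    """

    id: str
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 1 or self.codes.size < 1:
            raise ValueError("empty sequence")
        if self.codes.min() < 0 or self.codes.max() >= ALPHABET_SIZE:
            raise ValueError("residue codes must lie in 0..20")

    def __len__(self) -> int:
        return int(self.codes.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinSequence):
            return NotImplemented
        return self.id == other.id and np.array_equal(self.codes, other.codes)

    def as_string(self) -> str:
        """Decode back to one-letter residue characters."""
        return decode_codes(self.codes)


@dataclass(frozen=True)
class StructureString:
    """Per-residue three-state secondary structure, one of H/E/C each."""

    states: str

    def __post_init__(self) -> None:
        bad = set(self.states) - set(STATES)
        if bad:
            raise ValueError(f"invalid state {sorted(bad)[0]!r}: expected only H, E, C")

    def __len__(self) -> int:
        return len(self.states)

    def to_indices(self) -> np.ndarray:
        """Integer view: H -> 0, E -> 1, C -> 2."""
        return np.fromiter((_STATE_INDEX[s] for s in self.states), dtype=np.int64, count=len(self.states))

    @classmethod
    def from_indices(cls, idx: np.ndarray) -> "StructureString":
        return cls("".join(STATES[i] for i in np.asarray(idx, dtype=np.int64)))


@dataclass
class TrainingRecord:
    """A (sequence, known structure) pair from the training database."""

    sequence: ProteinSequence
    structure: StructureString

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError(
                f"length mismatch in record {self.sequence.id!r}: "
                f"sequence {len(self.sequence)} vs structure {len(self.structure)}"
            )


@dataclass(frozen=True)
class StateProbabilities:
    """Normalized per-residue probabilities (pH, pE, pC)."""

    pH: float
    pE: float
    pC: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pH, self.pE, self.pC], dtype=np.float64)


def encode_sequence(raw: str, id: str = "") -> ProteinSequence:
    """Encode a raw amino-acid string into residue codes 0..20.

    Whitespace is removed and letters are uppercased first. Canonical amino
    acids map to 0..19 (alphabetical); any other letter maps to 20. A
    non-letter character is an error naming the character and its 1-based
    position in the cleaned string.
    """
    cleaned = "".join(raw.split()).upper()
    if not cleaned:
        raise ValueError("empty sequence")
    codes = np.empty(len(cleaned), dtype=np.int64)
    for i, ch in enumerate(cleaned):
        if not ch.isalpha():
            raise ValueError(f"non-letter character {ch!r} at position {i + 1}")
        codes[i] = _CODE_OF.get(ch, UNKNOWN_CODE)
    return ProteinSequence(id=id, codes=codes)


def decode_codes(codes: np.ndarray) -> str:
    """Inverse of encoding on the 21-symbol alphabet."""
    return "".join(SYMBOLS[int(c)] for c in codes)
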