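"""Readers and writers: FASTA input, paired training database, prediction output.

Formats
-------
FASTA
    Standard ``>`` headers, free line wrapping; the record id is the header
    token up to the first whitespace. Parsed with Biopython.
Training database
    A bespoke paired-record text format (no standard exists for paired
    sequence/structure text): each record is exactly three lines —
    ``>id``, the amino-acid sequence, and an equal-length structure line
    over {H, E, C}. Blank lines are ignored.
Prediction output
    Per sequence: a header line ``# <id>`` then one whitespace-delimited
    line per residue: 1-based position, residue character, predicted state,
    pH, pE, pC with 4 decimal places.
"""

from __future__ import annotations

import io as _io
import os
from contextlib import contextmanager
from typing import Iterator, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .alphabet import (
    ProteinSequence,
    StateProbabilities,
    StructureString,
    TrainingRecord,
    encode_sequence,
)


@contextmanager
def _open_text(source, mode: str = "r") -> Iterator:
    """Yield a text stream from a path or a file-like object."""
    if isinstance(source, (str, os.PathLike)):
        fh = open(source, mode)
        try:
            yield fh
        finally:
            fh.close()
    else:
        yield source


def read_fasta(source) -> list[ProteinSequence]:
    """Read all records of a FASTA file or stream, preserving order."""
    with _open_text(source) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(f"sequence line before any FASTA header: {line.strip()!r}")
            break
    records = []
    for title, seq in SimpleFastaParser(_io.StringIO(text)):
        rec_id = title.split()[0] if title.split() else ""
        if not seq.strip():
            raise ValueError(f"empty sequence in FASTA record {rec_id!r}")
        records.append(encode_sequence(seq, id=rec_id))
    if not records:
        raise ValueError("no FASTA records found")
    return records


def read_training_db(source) -> list[TrainingRecord]:
    """Read the paired sequence/structure training database."""
    with _open_text(source) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    records: list[TrainingRecord] = []
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise ValueError(f"expected '>' header, got {header!r}")
        rec_id = header[1:].split()[0] if header[1:].split() else ""
        if i + 2 >= len(lines):
            raise ValueError(f"truncated record {rec_id!r}: need sequence and structure lines")
        seq_line, struct_line = lines[i + 1].strip(), lines[i + 2].strip()
        if len(seq_line) != len(struct_line):
            raise ValueError(
                f"length mismatch in record {rec_id!r}: "
                f"sequence {len(seq_line)} vs structure {len(struct_line)}"
            )
        bad = set(struct_line) - set("HEC")
        if bad:
            raise ValueError(f"invalid state {sorted(bad)[0]!r} in record {rec_id!r}")
        records.append(
            TrainingRecord(
                sequence=encode_sequence(seq_line, id=rec_id),
                structure=StructureString(struct_line),
            )
        )
        i += 3
    if not records:
        raise ValueError("no training records found")
    return records


def write_training_db(records: Sequence[TrainingRecord], dest) -> None:
    """Write records in the 3-line paired format read_training_db accepts."""
    with _open_text(dest, "w") as fh:
        for rec in records:
            fh.write(f">{rec.sequence.id}\n{rec.sequence.as_string()}\n{rec.structure.states}\n")


def _prob_matrix(probs) -> np.ndarray:
    """Coerce probabilities to an (N, 3) float array (rows pH, pE, pC)."""
    if isinstance(probs, np.ndarray):
        mat = np.asarray(probs, dtype=np.float64)
    else:
        mat = np.asarray(
            [p.as_array() if isinstance(p, StateProbabilities) else np.asarray(p, dtype=np.float64) for p in probs]
        )
    if mat.ndim != 2 or mat.shape[1] != 3:
        raise ValueError("probabilities must form an (N, 3) matrix")
    return mat


def write_prediction(sequence: ProteinSequence, states: StructureString, probs, dest) -> None:
    """Write one predicted record: header then per-residue state and probabilities."""
    mat = _prob_matrix(probs)
    if not (len(sequence) == len(states) == mat.shape[0]):
        raise ValueError(
            f"length mismatch for {sequence.id!r}: sequence {len(sequence)}, "
            f"states {len(states)}, probabilities {mat.shape[0]}"
        )
    chars = sequence.as_string()
    with _open_text(dest, "a" if _is_open_stream(dest) else "w") as fh:
        fh.write(f"# {sequence.id}\n")
        for i in range(len(sequence)):
            pH, pE, pC = mat[i]
            fh.write(f"{i + 1} {chars[i]} {states.states[i]} {pH:.4f} {pE:.4f} {pC:.4f}\n")


def _is_open_stream(dest) -> bool:
    return not isinstance(dest, (str, os.PathLike))


def read_prediction(source) -> list[tuple[str, str, StructureString, np.ndarray]]:
    """Parse a prediction file back into (id, residues, states, probabilities)."""
    with _open_text(source) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    out = []
    cur_id = None
    chars: list[str] = []
    states: list[str] = []
    probs: list[list[float]] = []

    def flush():
        if cur_id is not None:
            out.append((cur_id, "".join(chars), StructureString("".join(states)), np.asarray(probs)))

    for ln in lines:
        if ln.startswith("#"):
            flush()
            cur_id = ln[1:].strip()
            chars, states, probs = [], [], []
        else:
            if cur_id is None:
                raise ValueError("prediction data before any '# id' header")
            parts = ln.split()
            if len(parts) != 6:
                raise ValueError(f"malformed prediction line: {ln!r}")
            chars.append(parts[1])
            states.append(parts[2])
            probs.append([float(parts[3]), float(parts[4]), float(parts[5])])
    flush()
    if not out:
        raise ValueError("no prediction records found")
    return out
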