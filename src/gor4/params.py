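"""Training statistics, information tables, segmentation, quantization, model file.

The model consists of two tables of information differences in natural-log
units, estimated from a database of (sequence, structure) pairs over a
17-residue window (8 neighbors on each side of the target residue):

``dir[s][m][r]``
    Directional (singlet) information: evidence that the residue type ``r``
    observed at window offset ``m`` (0..16) lends to state ``s`` at the
    window center, as the smoothed log likelihood ratio

        ln((c_s + d) / (c_!s + d)) + ln((n_!s + d) / (n_s + d))

    where ``c_s`` counts occurrences of ``r`` at offset ``m`` in windows
    whose center is in state ``s``, ``c_!s`` pools the other two states,
    ``n_s``/``n_!s`` are total window counts per class and ``d`` is a
    pseudocount.

``pairinfo[s][p][r1][r2]``
    Pairwise information for the ordered residue types ``(r1, r2)`` at the
    unordered window-position pair with index ``p`` (0..135), same formula
    with pair counts.

Storage conventions match the table geometry of the original GOR-IV
parameter tables (*infor_dir*, *infor_pair*): 21-symbol alphabet, C(17,2) =
136 position pairs, and one address packing the three state values. At
double precision one state's pair table is exactly 21*21*136*8 bytes
(468 KB after flooring to kilobytes); segmented access splits it into 136
independently addressable parts, one per position pair. Tables may be
quantized to 32-bit integers with a recorded scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import BinaryIO, Sequence

import numpy as np

from .alphabet import ALPHABET_SIZE, N_STATES, UNKNOWN_CODE, TrainingRecord

#: Window width (residues of context per position).
WINDOW = 17
#: Neighbors considered on each side of the target residue.
HALF_WINDOW = 8
#: Number of unordered window-position pairs, C(17, 2).
N_PAIRS = 136

DIR_SHAPE = (N_STATES, WINDOW, ALPHABET_SIZE)
PAIR_SHAPE = (N_STATES, N_PAIRS, ALPHABET_SIZE, ALPHABET_SIZE)

_MAGIC = b"GOR4TBL\x00"
_FORMAT_VERSION = 1


def pair_index(j1: int, j2: int) -> int:
    """Lexicographic index of the unordered window-position pair (j1, j2).

    j1 < j2, both in 0..16; (0,1) -> 0, ..., (15,16) -> 135.
    """
    if not (0 <= j1 < WINDOW and 0 <= j2 < WINDOW):
        raise ValueError(f"window positions out of range: ({j1}, {j2})")
    if j1 >= j2:
        raise ValueError(f"pair requires j1 < j2, got ({j1}, {j2})")
    return j1 * WINDOW - j1 * (j1 + 1) // 2 + (j2 - j1 - 1)


def pair_positions(p: int) -> tuple[int, int]:
    """Inverse of :func:`pair_index`."""
    if not (0 <= p < N_PAIRS):
        raise ValueError(f"pair index out of range: {p}")
    return _PAIR_J1[p], _PAIR_J2[p]


def _build_pair_maps() -> tuple[np.ndarray, np.ndarray]:
    j1s = np.empty(N_PAIRS, dtype=np.int64)
    j2s = np.empty(N_PAIRS, dtype=np.int64)
    p = 0
    for a in range(WINDOW):
        for b in range(a + 1, WINDOW):
            j1s[p], j2s[p] = a, b
            p += 1
    return j1s, j2s


#: Position pair p -> (earlier, later) window positions.
_PAIR_J1, _PAIR_J2 = _build_pair_maps()
PAIR_J1, PAIR_J2 = _PAIR_J1, _PAIR_J2


@dataclass
class TrainingCounts:
    """Raw occurrence counts from the training database.

    singlet[s][m][r]: residue r at window offset m around a position in
    state s; pair[s][p][r1][r2]: ordered residue pair at position pair p;
    n_state[s]: number of positions observed in state s.
    """

    singlet: np.ndarray
    pair: np.ndarray
    n_state: np.ndarray

    @classmethod
    def zeros(cls) -> "TrainingCounts":
        return cls(
            singlet=np.zeros(DIR_SHAPE, dtype=np.int64),
            pair=np.zeros(PAIR_SHAPE, dtype=np.int64),
            n_state=np.zeros(N_STATES, dtype=np.int64),
        )

    def __add__(self, other: "TrainingCounts") -> "TrainingCounts":
        return TrainingCounts(
            singlet=self.singlet + other.singlet,
            pair=self.pair + other.pair,
            n_state=self.n_state + other.n_state,
        )


class InformationTables:
    """The trained model: directional and pairwise information differences.

    Values are stored either as float64 (nats) or, when ``quantized``, as
    int32 with ``value = stored / scale``. The float view used for
    prediction is exposed by :attr:`dir` and :attr:`pairinfo`.
    """

    window = WINDOW
    alphabet_size = ALPHABET_SIZE
    n_pairs = N_PAIRS

    def __init__(self, dir_values: np.ndarray, pair_values: np.ndarray,
                 quantized: bool = False, scale: float = 1.0):
        dir_values = np.asarray(dir_values)
        pair_values = np.asarray(pair_values)
        if dir_values.shape != DIR_SHAPE:
            raise ValueError(f"dir table must have shape {DIR_SHAPE}, got {dir_values.shape}")
        if pair_values.shape != PAIR_SHAPE:
            raise ValueError(f"pair table must have shape {PAIR_SHAPE}, got {pair_values.shape}")
        if quantized:
            if scale <= 0:
                raise ValueError("quantization scale must be positive")
            dir_values = dir_values.astype(np.int32)
            pair_values = pair_values.astype(np.int32)
        else:
            dir_values = dir_values.astype(np.float64)
            pair_values = pair_values.astype(np.float64)
        if not quantized and not (np.isfinite(dir_values).all() and np.isfinite(pair_values).all()):
            raise ValueError("information tables must be finite")
        self.dir_raw = dir_values
        self.pair_raw = pair_values
        self.quantized = bool(quantized)
        self.scale = float(scale)
        self._dir_f: np.ndarray | None = None
        self._pair_f: np.ndarray | None = None

    @property
    def dir(self) -> np.ndarray:
        """Directional table as float64 nats (dequantized if needed)."""
        if not self.quantized:
            return self.dir_raw
        if self._dir_f is None:
            self._dir_f = self.dir_raw.astype(np.float64) / self.scale
        return self._dir_f

    @property
    def pairinfo(self) -> np.ndarray:
        """Pair table as float64 nats (dequantized if needed)."""
        if not self.quantized:
            return self.pair_raw
        if self._pair_f is None:
            self._pair_f = self.pair_raw.astype(np.float64) / self.scale
        return self._pair_f

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InformationTables):
            return NotImplemented
        return (
            self.quantized == other.quantized
            and self.scale == other.scale
            and np.array_equal(self.dir_raw, other.dir_raw)
            and np.array_equal(self.pair_raw, other.pair_raw)
        )


def accumulate_counts(db: Sequence[TrainingRecord]) -> TrainingCounts:
    """Accumulate singlet and pair counts over every position of every record.

    For each residue position t in state s, the 17-residue window centered
    at t (out-of-sequence positions read as 'X', code 20) contributes 17
    singlet increments and 136 pair increments to state s.
    """
    if not db:
        raise ValueError("empty training database")
    counts = TrainingCounts.zeros()
    offsets = np.arange(WINDOW)
    for rec in db:
        codes = rec.sequence.codes
        n = codes.size
        padded = np.full(n + 2 * HALF_WINDOW, UNKNOWN_CODE, dtype=np.int64)
        padded[HALF_WINDOW:HALF_WINDOW + n] = codes
        win = np.lib.stride_tricks.sliding_window_view(padded, WINDOW)  # (n, 17)
        s_idx = rec.structure.to_indices()
        np.add.at(counts.singlet, (s_idx[:, None], offsets[None, :], win), 1)
        np.add.at(
            counts.pair,
            (s_idx[:, None], np.arange(N_PAIRS)[None, :], win[:, _PAIR_J1], win[:, _PAIR_J2]),
            1,
        )
        np.add.at(counts.n_state, s_idx, 1)
    return counts


def counts_to_information(counts: TrainingCounts, delta: float = 1.0) -> InformationTables:
    """Convert raw counts into smoothed information-difference tables.

    Each entry contrasts a state against the pooled other two states:
    ln((c_s + delta)/(c_!s + delta)) + ln((n_!s + delta)/(n_s + delta)).
    ``delta`` > 0 guarantees finiteness on any training set.
    """
    if delta <= 0:
        raise ValueError("pseudocount delta must be positive")
    n_total = counts.n_state.sum()
    dir_t = np.empty(DIR_SHAPE)
    pair_t = np.empty(PAIR_SHAPE)
    for s in range(N_STATES):
        n_s = counts.n_state[s]
        n_not = n_total - n_s
        prior = np.log((n_not + delta) / (n_s + delta))
        sing_not = counts.singlet.sum(axis=0) - counts.singlet[s]
        pair_not = counts.pair.sum(axis=0) - counts.pair[s]
        dir_t[s] = np.log((counts.singlet[s] + delta) / (sing_not + delta)) + prior
        pair_t[s] = np.log((counts.pair[s] + delta) / (pair_not + delta)) + prior
    return InformationTables(dir_t, pair_t)


def train(db: Sequence[TrainingRecord], delta: float = 1.0) -> InformationTables:
    """Convenience wrapper: accumulate counts and build the tables."""
    return counts_to_information(accumulate_counts(db), delta=delta)


def quantize_tables(tables: InformationTables, scale: float = 65536.0) -> InformationTables:
    """Store table values as round-to-nearest scaled 32-bit integers.

    Rounding is half-away-from-zero; the dequantization error is at most
    0.5/scale per entry. Raises on 32-bit overflow.
    """
    if tables.quantized:
        raise ValueError("tables are already quantized")
    if scale <= 0:
        raise ValueError("quantization scale must be positive")
    max_mag = max(np.abs(tables.dir_raw).max(), np.abs(tables.pair_raw).max())
    if max_mag * scale > np.iinfo(np.int32).max:
        raise OverflowError(
            f"scaled magnitude {max_mag * scale:.6g} exceeds the signed 32-bit range "
            f"(largest table value {max_mag:.6g} at scale {scale:g})"
        )

    def _q(v: np.ndarray) -> np.ndarray:
        return np.trunc(v * scale + np.copysign(0.5, v)).astype(np.int32)

    return InformationTables(_q(tables.dir_raw), _q(tables.pair_raw), quantized=True, scale=scale)


def dequantize_tables(tables: InformationTables) -> InformationTables:
    """Return a float-valued copy of a quantized table set."""
    if not tables.quantized:
        raise ValueError("tables are not quantized")
    return InformationTables(tables.dir, tables.pairinfo)


@dataclass
class SegmentedTables:
    """The pair table split into 136 independently addressable segments.

    Segment p holds pairinfo[:, p, :, :] for all three states, mirroring
    the parallel-access layout where each position pair lives in its own
    memory bank. The segments partition the pair table exactly.
    """

    segments: list[np.ndarray]
    dir: np.ndarray

    def fetch_segment(self, p: int, r1: int, r2: int) -> np.ndarray:
        """3-state value vector for (r1, r2) at position-pair p."""
        return self.segments[p][:, r1, r2]

    def reassemble(self) -> np.ndarray:
        """Stack the segments back into the full pair table."""
        return np.stack(self.segments, axis=1)


def segment_pair_table(tables: InformationTables) -> SegmentedTables:
    """Split the pair table into its 136 per-position-pair segments."""
    pair = tables.pairinfo if not tables.quantized else tables.pair_raw
    return SegmentedTables(
        segments=[pair[:, p, :, :].copy() for p in range(N_PAIRS)],
        dir=(tables.dir if not tables.quantized else tables.dir_raw).copy(),
    )


def pair_table_bytes(tables: InformationTables | None = None, per_state: bool = True) -> int:
    """Byte size of the pair table at double precision (per state or total)."""
    per = ALPHABET_SIZE * ALPHABET_SIZE * N_PAIRS * 8
    return per if per_state else N_STATES * per


def save_model(tables: InformationTables, path) -> None:
    """Write the bespoke little-endian binary model file (``.gor4``)."""
    header = bytearray()
    header += _MAGIC
    header += np.array(
        [_FORMAT_VERSION, WINDOW, ALPHABET_SIZE, N_PAIRS], dtype="<u4"
    ).tobytes()
    header += np.array([1 if tables.quantized else 0], dtype="<u1").tobytes()
    header += b"\x00\x00\x00"
    header += np.array([tables.scale], dtype="<f8").tobytes()
    dtype = "<i4" if tables.quantized else "<f8"
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(tables.dir_raw.astype(dtype).tobytes(order="C"))
        fh.write(tables.pair_raw.astype(dtype).tobytes(order="C"))


def _read_exact(fh: BinaryIO, n: int) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise ValueError("unexpected end of model file")
    return buf


def load_model(path) -> InformationTables:
    """Read a model file written by :func:`save_model`; round-trip is bit-exact."""
    with open(path, "rb") as fh:
        magic = _read_exact(fh, 8)
        if magic != _MAGIC:
            raise ValueError(f"bad magic {magic!r}: not a gor4 model file")
        version, w, a, n_pairs = np.frombuffer(_read_exact(fh, 16), dtype="<u4")
        if version != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {int(version)}; this reader understands version {_FORMAT_VERSION}"
            )
        if (w, a, n_pairs) != (WINDOW, ALPHABET_SIZE, N_PAIRS):
            raise ValueError(
                f"unexpected table geometry (w={int(w)}, A={int(a)}, pairs={int(n_pairs)}); "
                f"expected (w={WINDOW}, A={ALPHABET_SIZE}, pairs={N_PAIRS})"
            )
        quantized = bool(_read_exact(fh, 1)[0])
        _read_exact(fh, 3)
        scale = float(np.frombuffer(_read_exact(fh, 8), dtype="<f8")[0])
        dtype = np.dtype("<i4") if quantized else np.dtype("<f8")
        n_dir = int(np.prod(DIR_SHAPE))
        n_pair = int(np.prod(PAIR_SHAPE))
        dir_v = np.frombuffer(_read_exact(fh, n_dir * dtype.itemsize), dtype=dtype).reshape(DIR_SHAPE)
        pair_v = np.frombuffer(_read_exact(fh, n_pair * dtype.itemsize), dtype=dtype).reshape(PAIR_SHAPE)
        if fh.read(1):
            raise ValueError("trailing bytes after model payload")
    return InformationTables(dir_v, pair_v, quantized=quantized, scale=scale if quantized else 1.0)
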