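"""The prediction stage: window sums, softmax normalization, state selection.

For the residue at position t the predictor reads a 17-residue window
(8 neighbors each side; out-of-sequence positions read the boundary symbol
X) and forms, per state s, the information sum

    I_s = (2/17) * sum_{j1<j2} pairinfo[s][p(j1,j2)][w[j1]][w[j2]]
        - (15/17) * sum_j dir[s][j][w[j]]

The coefficients make the expression collapse to the plain singlet sum when
the pair information degenerates to the sum of its two singlet terms
(each singlet appears in 16 pairs: 2/17*16 - 15/17 = 1). The three sums are
turned into probabilities with an overflow-safe softmax and the largest
probability names the state (ties broken H > E > C).

Two summation engines are provided. The streaming engine mirrors the
accelerator's access pattern: it enumerates *ordered* position pairs (j, k),
j != k, reading one packed 3-state pair-table entry per ordered pair with
weight 1/17 — 17*16 = 272 pair reads per residue, algebraically equal to the
2/17-weighted unordered sum. The naive reference engine reads each unordered
pair once (136 reads). Both must agree to floating-point roundoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import (
    N_STATES,
    ProteinSequence,
    StateProbabilities,
    StructureString,
    UNKNOWN_CODE,
)
from .params import (
    HALF_WINDOW,
    InformationTables,
    N_PAIRS,
    PAIR_J1,
    PAIR_J2,
    WINDOW,
)

#: Ordered position pairs (j, k), j != k, in row-major (j, k) order, and the
#: unordered pair index each one reads. 272 entries.
_ORD_J = np.array([j for j in range(WINDOW) for k in range(WINDOW) if j != k], dtype=np.int64)
_ORD_K = np.array([k for j in range(WINDOW) for k in range(WINDOW) if j != k], dtype=np.int64)


def _ord_pair_index() -> np.ndarray:
    lut = np.zeros((WINDOW, WINDOW), dtype=np.int64)
    for p in range(N_PAIRS):
        lut[PAIR_J1[p], PAIR_J2[p]] = p
        lut[PAIR_J2[p], PAIR_J1[p]] = p
    return lut[_ORD_J, _ORD_K]


_ORD_P = _ord_pair_index()
# A packed entry is addressed by (earlier-position residue, later-position
# residue); an ordered read (j, k) with j > k therefore reads entry
# (p(k, j), w[k], w[j]) — the same address as its unordered counterpart.
_ORD_LO = np.minimum(_ORD_J, _ORD_K)
_ORD_HI = np.maximum(_ORD_J, _ORD_K)

#: Reads per residue under the streaming (ordered-pair) engine.
PAIR_READS_PER_RESIDUE = WINDOW * (WINDOW - 1)  # 272
DIR_READS_PER_RESIDUE = WINDOW

_PAIR_COEF = 2.0 / WINDOW
_DIR_COEF = (WINDOW - 2) / WINDOW


@dataclass
class LookupStats:
    """Instrumentation counters for parameter-table traffic.

    One "read" is one table-address access returning the packed 3-state
    value vector; the streaming engine performs 272 pair reads and 17
    directional reads per residue.
    """

    pair_reads: int = 0
    dir_reads: int = 0
    residues_processed: int = 0

    def merge(self, other: "LookupStats") -> None:
        self.pair_reads += other.pair_reads
        self.dir_reads += other.dir_reads
        self.residues_processed += other.residues_processed


def extract_window(seq: ProteinSequence, t: int) -> np.ndarray:
    """17-residue window centered on position t, padded with code 20."""
    n = len(seq)
    if not (0 <= t < n):
        raise ValueError(f"position {t} out of range for sequence of length {n}")
    window = np.full(WINDOW, UNKNOWN_CODE, dtype=np.int64)
    lo = max(0, t - HALF_WINDOW)
    hi = min(n, t + HALF_WINDOW + 1)
    window[lo - (t - HALF_WINDOW):hi - (t - HALF_WINDOW)] = seq.codes[lo:hi]
    return window


def window_matrix(codes: np.ndarray) -> np.ndarray:
    """All N windows of a sequence as an (N, 17) matrix."""
    n = codes.size
    padded = np.full(n + 2 * HALF_WINDOW, UNKNOWN_CODE, dtype=np.int64)
    padded[HALF_WINDOW:HALF_WINDOW + n] = codes
    return np.lib.stride_tricks.sliding_window_view(padded, WINDOW)


def information_sum(window: np.ndarray, tables: InformationTables, s: int) -> float:
    """Naive (unordered-pair) information sum for one window and state."""
    window = np.asarray(window, dtype=np.int64)
    if window.shape != (WINDOW,):
        raise ValueError(f"window must hold exactly {WINDOW} residue codes")
    pair_part = tables.pairinfo[s, np.arange(N_PAIRS), window[PAIR_J1], window[PAIR_J2]].sum()
    dir_part = tables.dir[s, np.arange(WINDOW), window].sum()
    return float(_PAIR_COEF * pair_part - _DIR_COEF * dir_part)


def information_sums_streaming(
    window: np.ndarray, tables: InformationTables, stats: LookupStats | None = None
) -> np.ndarray:
    """All three information sums via the ordered-pair streaming engine."""
    window = np.asarray(window, dtype=np.int64)
    pair_part = tables.pairinfo[:, _ORD_P, window[_ORD_LO], window[_ORD_HI]].sum(axis=1) / WINDOW
    dir_part = tables.dir[:, np.arange(WINDOW), window].sum(axis=1)
    if stats is not None:
        stats.pair_reads += PAIR_READS_PER_RESIDUE
        stats.dir_reads += DIR_READS_PER_RESIDUE
        stats.residues_processed += 1
    return pair_part - _DIR_COEF * dir_part


def normalize(i_h: float, i_e: float, i_c: float) -> StateProbabilities:
    """Softmax of the three information sums, shifted by the max for safety."""
    arr = np.array([i_h, i_e, i_c], dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("information sums must be finite")
    p = _softmax_rows(arr[None, :])[0]
    return StateProbabilities(pH=float(p[0]), pE=float(p[1]), pC=float(p[2]))


def _softmax_rows(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def select_state(p: StateProbabilities) -> str:
    """Largest-probability state; ties resolved by the priority H > E > C."""
    return "HEC"[int(np.argmax(p.as_array()))]


def predict_probabilities(
    seq: ProteinSequence,
    tables: InformationTables,
    stats: LookupStats | None = None,
    engine: str = "streaming",
) -> np.ndarray:
    """Per-residue state probabilities as an (N, 3) matrix (rows pH, pE, pC).

    ``engine`` selects the summation path: "streaming" (ordered pairs, 272
    packed reads per residue, instrumented) or "reference" (unordered
    pairs, 136 reads per residue).
    """
    if len(seq) < 1:
        raise ValueError("empty sequence")
    win = window_matrix(seq.codes)  # (N, 17)
    n = win.shape[0]
    dir_part = tables.dir[:, np.arange(WINDOW), win].sum(axis=2)  # (3, N)
    if engine == "streaming":
        pair_part = tables.pairinfo[:, _ORD_P, win[:, _ORD_LO], win[:, _ORD_HI]].sum(axis=2) / WINDOW
        if stats is not None:
            stats.pair_reads += PAIR_READS_PER_RESIDUE * n
            stats.dir_reads += DIR_READS_PER_RESIDUE * n
            stats.residues_processed += n
    elif engine == "reference":
        pair_part = _PAIR_COEF * tables.pairinfo[
            :, np.arange(N_PAIRS), win[:, PAIR_J1], win[:, PAIR_J2]
        ].sum(axis=2)
        if stats is not None:
            stats.pair_reads += N_PAIRS * n
            stats.dir_reads += DIR_READS_PER_RESIDUE * n
            stats.residues_processed += n
    else:
        raise ValueError(f"unknown engine {engine!r}")
    scores = (pair_part - _DIR_COEF * dir_part).T  # (N, 3)
    return _softmax_rows(scores)


def predict_sequence(
    seq: ProteinSequence,
    tables: InformationTables,
    stats: LookupStats | None = None,
    engine: str = "streaming",
) -> tuple[StructureString, list[StateProbabilities]]:
    """Preliminary per-residue prediction for one sequence.

    Returns the argmax state string and the per-residue probabilities.
    """
    probs = predict_probabilities(seq, tables, stats=stats, engine=engine)
    states = StructureString.from_indices(np.argmax(probs, axis=1))
    return states, [StateProbabilities(*row) for row in probs]
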