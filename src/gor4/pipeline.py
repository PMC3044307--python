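"""Three-stage streaming pipeline: prediction feeding parallel correction channels.

The accelerator's task pipeline becomes three worker roles connected by
bounded queues: a single prediction worker streams preliminary results into
a buffer, several correction channels (each running the two scanning passes
back to back) pick sequences up first-free, and a collector records results
as they complete. Results are bit-identical to the serial path for every
channel count and buffer size; only completion order may vary. Output can
be emitted in completion order (FCFS, as the hardware wrote DRAM) or
reordered to input order for byte-reproducible files.
"""

from __future__ import annotations

import queue
import threading
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alphabet import ProteinSequence, StructureString
from .correct import CorrectionConfig, correction_pass1, correction_pass2
from .params import InformationTables
from .predict import LookupStats, predict_probabilities


@dataclass(frozen=True)
class PipelineConfig:
    """Topology knobs: channel count, inter-stage buffer size, output order."""

    n_correction_channels: int = 2
    buffer_capacity: int = 4
    output_order: str = "fcfs"

    def __post_init__(self) -> None:
        if self.n_correction_channels < 1:
            raise ValueError("n_correction_channels must be >= 1")
        if self.buffer_capacity < 1:
            raise ValueError("buffer_capacity must be >= 1")
        if self.output_order not in ("fcfs", "input_order"):
            raise ValueError("output_order must be 'fcfs' or 'input_order'")


@dataclass
class PipelineResult:
    """Final corrected structure for one input sequence."""

    id: str
    states: StructureString
    probs: np.ndarray  # (N, 3) rows (pH, pE, pC)
    completion_ordinal: int


@dataclass
class StageStats:
    """Sequences processed by each pipeline stage."""

    predicted: int = 0
    corrected_pass1: int = 0
    corrected_pass2: int = 0


_DONE = object()


def run_pipeline(
    seqs: Sequence[ProteinSequence],
    tables: InformationTables,
    cfg: PipelineConfig = PipelineConfig(),
    ccfg: CorrectionConfig = CorrectionConfig(),
) -> tuple[list[PipelineResult], LookupStats, StageStats]:
    """Run prediction + both corrections over all sequences through the pipeline.

    The result multiset (keyed by id) is identical to the serial path for
    every configuration; with output_order='input_order' the list order
    equals input order.
    """
    if not seqs:
        raise ValueError("empty input: no sequences to predict")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})[0]
        raise ValueError(f"duplicate sequence id {dup!r}")

    pred_q: queue.Queue = queue.Queue(maxsize=cfg.buffer_capacity)
    out_q: queue.Queue = queue.Queue()
    stats = LookupStats()
    stage = StageStats()
    lock = threading.Lock()
    errors: list[BaseException] = []

    def predictor() -> None:
        try:
            for idx, seq in enumerate(seqs):
                probs = predict_probabilities(seq, tables, stats=stats)
                states = StructureString.from_indices(np.argmax(probs, axis=1))
                with lock:
                    stage.predicted += 1
                pred_q.put((idx, seq.id, states, probs))
        except BaseException as exc:  # surfaced after join
            errors.append(exc)
        finally:
            for _ in range(cfg.n_correction_channels):
                pred_q.put(_DONE)

    def corrector() -> None:
        while True:
            item = pred_q.get()
            if item is _DONE:
                break
            idx, seq_id, states, probs = item
            try:
                states = correction_pass1(states, probs, ccfg)
                with lock:
                    stage.corrected_pass1 += 1
                states = correction_pass2(states, ccfg)
                with lock:
                    stage.corrected_pass2 += 1
                out_q.put((idx, seq_id, states, probs))
            except BaseException as exc:  # keep draining so the predictor never blocks
                errors.append(exc)
        out_q.put(_DONE)

    threads = [threading.Thread(target=predictor, name="gor4-predict")]
    threads += [
        threading.Thread(target=corrector, name=f"gor4-correct-{c}")
        for c in range(cfg.n_correction_channels)
    ]
    for t in threads:
        t.start()

    results: list[PipelineResult] = []
    finished_channels = 0
    while len(results) < len(seqs) and finished_channels < cfg.n_correction_channels:
        item = out_q.get()
        if item is _DONE:
            finished_channels += 1
            continue
        idx, seq_id, states, probs = item
        results.append(PipelineResult(id=seq_id, states=states, probs=probs, completion_ordinal=len(results)))
    for t in threads:
        t.join()
    if errors:
        raise errors[0]

    if cfg.output_order == "input_order":
        order = {sid: i for i, sid in enumerate(ids)}
        results.sort(key=lambda r: order[r.id])
    return results, stats, stage


def run_serial(
    seqs: Sequence[ProteinSequence],
    tables: InformationTables,
    ccfg: CorrectionConfig = CorrectionConfig(),
) -> list[PipelineResult]:
    """Reference path: predict and correct each sequence in input order."""
    if not seqs:
        raise ValueError("empty input: no sequences to predict")
    results = []
    for i, seq in enumerate(seqs):
        probs = predict_probabilities(seq, tables)
        states = StructureString.from_indices(np.argmax(probs, axis=1))
        states = correction_pass2(correction_pass1(states, probs, ccfg), ccfg)
        results.append(PipelineResult(id=seq.id, states=states, probs=probs, completion_ordinal=i))
    return results
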