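"""Table geometry, count accumulation, information formula, quantization, model file."""

import numpy as np
import pytest

from gor4 import (
    InformationTables,
    StructureString,
    TrainingCounts,
    accumulate_counts,
    counts_to_information,
    dequantize_tables,
    encode_sequence,
    load_model,
    pair_index,
    pair_positions,
    pair_table_bytes,
    quantize_tables,
    save_model,
    segment_pair_table,
)
from gor4.alphabet import TrainingRecord
from gor4.params import DIR_SHAPE, N_PAIRS, PAIR_SHAPE, WINDOW


class TestPairIndex:
    @pytest.mark.parametrize("j1, j2, p", [(0, 1, 0), (15, 16, 135), (0, 16, 15), (1, 2, 16)])
    def test_examples(self, j1, j2, p):
        assert pair_index(j1, j2) == p

    def test_bijection_with_inverse(self):
        seen = set()
        for j1 in range(WINDOW):
            for j2 in range(j1 + 1, WINDOW):
                p = pair_index(j1, j2)
                assert 0 <= p < N_PAIRS
                assert pair_positions(p) == (j1, j2)
                seen.add(p)
        assert seen == set(range(N_PAIRS))

    @pytest.mark.parametrize("j1, j2", [(3, 3), (5, 2), (-1, 4), (0, 17)])
    def test_invalid_pairs(self, j1, j2):
        with pytest.raises(ValueError):
            pair_index(j1, j2)


def _lone_record(state="H"):
    return TrainingRecord(sequence=encode_sequence("A", id="one"), structure=StructureString(state))


class TestAccumulateCounts:
    def test_lone_residue_fully_padded(self):
        counts = accumulate_counts([_lone_record()])
        assert counts.n_state.tolist() == [1, 0, 0]
        assert counts.singlet[0, 8, 0] == 1  # the residue itself at the center
        for m in range(WINDOW):
            if m != 8:
                assert counts.singlet[0, m, 20] == 1  # padding everywhere else

    def test_one_pair_increment_per_pair_index(self):
        counts = accumulate_counts([_lone_record()])
        assert counts.pair[0].sum() == N_PAIRS
        assert counts.pair[0].reshape(N_PAIRS, -1).sum(axis=1).tolist() == [1] * N_PAIRS

    def test_additivity(self, small_dataset):
        both = accumulate_counts(small_dataset[:2])
        sep = accumulate_counts([small_dataset[0]]) + accumulate_counts([small_dataset[1]])
        assert np.array_equal(both.singlet, sep.singlet)
        assert np.array_equal(both.pair, sep.pair)
        assert np.array_equal(both.n_state, sep.n_state)

    def test_count_invariants(self, small_dataset):
        counts = accumulate_counts(small_dataset)
        total = sum(len(r.sequence) for r in small_dataset)
        assert counts.n_state.sum() == total
        # each window offset / pair index sees every counted position once
        assert np.array_equal(counts.singlet.sum(axis=2), np.tile(counts.n_state[:, None], (1, WINDOW)))
        assert np.array_equal(counts.pair.sum(axis=(2, 3)), np.tile(counts.n_state[:, None], (1, N_PAIRS)))

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            accumulate_counts([])


class TestInformationFormula:
    def test_symmetric_evidence_is_zero(self):
        counts = TrainingCounts.zeros()
        counts.singlet[:] = 5
        counts.pair[:] = 2
        counts.n_state[:] = 50  # n_notS = 100 != n_s, prior term nonzero but equal counts
        counts.singlet[0] = counts.singlet[1] + counts.singlet[2]
        counts.pair[0] = counts.pair[1] + counts.pair[2]
        counts.n_state[0] = counts.n_state[1] + counts.n_state[2]
        tables = counts_to_information(counts)
        assert np.allclose(tables.dir[0], 0.0)
        assert np.allclose(tables.pairinfo[0], 0.0)

    def test_two_to_one_ratio_gives_ln2(self):
        counts = TrainingCounts.zeros()
        k = 1000
        counts.singlet[0, :, :] = 2 * k
        counts.singlet[1, :, :] = k // 2
        counts.singlet[2, :, :] = k // 2
        counts.pair[:] = 1
        counts.n_state[:] = [10, 5, 5]  # n_s == n_notS, so the prior term vanishes
        tables = counts_to_information(counts, delta=1e-9)
        assert np.allclose(tables.dir[0], np.log(2.0), atol=1e-6)

    def test_zero_counts_finite_with_default_pseudocount(self):
        counts = accumulate_counts([_lone_record()])
        tables = counts_to_information(counts, delta=1.0)
        assert np.isfinite(tables.dir).all()
        assert np.isfinite(tables.pairinfo).all()

    def test_nonpositive_pseudocount_rejected(self):
        counts = accumulate_counts([_lone_record()])
        for bad in (0.0, -1.0):
            with pytest.raises(ValueError, match="pseudocount"):
                counts_to_information(counts, delta=bad)

    def test_swapping_state_and_complement_negates_entries(self, rng):
        """Two-state collapse antisymmetry: exchanging s with not-s flips signs."""
        counts = TrainingCounts.zeros()
        counts.singlet[0] = rng.integers(0, 40, size=DIR_SHAPE[1:])
        counts.singlet[1] = 2 * rng.integers(0, 20, size=DIR_SHAPE[1:])
        counts.singlet[2] = counts.singlet[1] // 2
        counts.singlet[1] -= counts.singlet[2]
        counts.pair[0] = rng.integers(0, 40, size=PAIR_SHAPE[1:])
        counts.pair[1] = rng.integers(0, 20, size=PAIR_SHAPE[1:])
        counts.pair[2] = rng.integers(0, 20, size=PAIR_SHAPE[1:])
        counts.n_state[:] = [30, 17, 13]

        swapped = TrainingCounts.zeros()
        swapped.singlet[0] = counts.singlet[1] + counts.singlet[2]
        swapped.singlet[1] = counts.singlet[0]  # complement split arbitrarily
        swapped.pair[0] = counts.pair[1] + counts.pair[2]
        swapped.pair[1] = counts.pair[0]
        swapped.n_state[:] = [counts.n_state[1] + counts.n_state[2], counts.n_state[0], 0]

        a = counts_to_information(counts, delta=1.0)
        b = counts_to_information(swapped, delta=1.0)
        assert np.allclose(b.dir[0], -a.dir[0])
        assert np.allclose(b.pairinfo[0], -a.pairinfo[0])


class TestQuantization:
    def test_exact_value(self):
        t = InformationTables(np.zeros(DIR_SHAPE), np.zeros(PAIR_SHAPE))
        t.dir_raw[0, 0, 0] = 1.0
        q = quantize_tables(t, scale=65536.0)
        assert q.quantized and q.scale == 65536.0
        assert q.dir_raw[0, 0, 0] == 65536
        assert q.dir_raw.dtype == np.int32

    def test_error_bound_on_random_tables(self, random_tables):
        t = random_tables()
        q = quantize_tables(t, scale=65536.0)
        d = dequantize_tables(q)
        bound = 0.5 / 65536.0 + 1e-15
        assert np.abs(d.dir - t.dir).max() <= bound
        assert np.abs(d.pairinfo - t.pairinfo).max() <= bound

    def test_overflow_reported(self, random_tables):
        t = random_tables(scale=100.0)
        with pytest.raises(OverflowError, match="32-bit"):
            quantize_tables(t, scale=2.0**31)

    def test_double_quantization_rejected(self, random_tables):
        q = quantize_tables(random_tables())
        with pytest.raises(ValueError):
            quantize_tables(q)


class TestSegmentation:
    def test_partition(self, random_tables):
        t = random_tables()
        seg = segment_pair_table(t)
        assert len(seg.segments) == 136
        assert np.array_equal(seg.reassemble(), t.pairinfo)

    def test_fetch_is_an_indexing_identity(self, random_tables):
        t = random_tables()
        seg = segment_pair_table(t)
        assert np.array_equal(seg.fetch_segment(0, 20, 20), t.pairinfo[:, 0, 20, 20])
        assert np.array_equal(seg.fetch_segment(135, 3, 7), t.pairinfo[:, 135, 3, 7])

    def test_segments_are_independent_copies(self, random_tables):
        t = random_tables()
        seg = segment_pair_table(t)
        seg.segments[0][:] = 0.0
        assert not np.array_equal(seg.segments[0], t.pairinfo[:, 0])
        assert np.array_equal(seg.segments[1], t.pairinfo[:, 1])


class TestTableBytes:
    def test_per_state_size_and_kilobytes(self):
        assert pair_table_bytes(per_state=True) == 21 * 21 * 136 * 8 == 479808
        assert pair_table_bytes(per_state=True) // 1024 == 468

    def test_whole_table_is_three_states(self):
        assert pair_table_bytes(per_state=False) == 3 * pair_table_bytes(per_state=True)


class TestModelFile:
    def test_round_trip_float(self, random_tables, tmp_path):
        t = random_tables()
        path = tmp_path / "m.gor4"
        save_model(t, path)
        assert load_model(path) == t

    def test_round_trip_quantized(self, random_tables, tmp_path):
        q = quantize_tables(random_tables())
        path = tmp_path / "q.gor4"
        save_model(q, path)
        back = load_model(path)
        assert back == q and back.scale == q.scale

    def test_truncated_file(self, random_tables, tmp_path):
        path = tmp_path / "m.gor4"
        save_model(random_tables(), path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError, match="unexpected end of model file"):
            load_model(path)

    def test_bad_magic(self, tmp_path):
        path = tmp_path / "bad.gor4"
        path.write_bytes(b"NOTMODEL" + b"\x00" * 64)
        with pytest.raises(ValueError, match="magic"):
            load_model(path)

    def test_version_mismatch_names_both_versions(self, random_tables, tmp_path):
        path = tmp_path / "m.gor4"
        save_model(random_tables(), path)
        data = bytearray(path.read_bytes())
        data[8:12] = np.array([99], dtype="<u4").tobytes()
        path.write_bytes(bytes(data))
        with pytest.raises(ValueError, match="99.*version 1"):
            load_model(path)
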