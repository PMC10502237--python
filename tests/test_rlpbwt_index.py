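"""Run-length column encoding, rank/FL navigation, index build and serialization."""

import numpy as np
import pytest

from mupbwt import panel_io, pbwt_core, rlpbwt_index
from mupbwt.rlpbwt_index import (
    SerializationError,
    build_index,
    compute_thresholds,
    deserialize,
    fl_map,
    index_stats,
    rank_before,
    rle_encode_column,
    serialize,
    symbol_at,
)

from conftest import random_instance

WORKED_COLUMN = np.array([int(c) for c in "00101111000000000000"], dtype=np.uint8)

# the total-integer budget: a fixed multiple of the O(r + h + w) bound
SPACE_CONSTANT = 32


def random_column(seed, h=40):
    return np.random.default_rng(seed).integers(0, 2, h).astype(np.uint8)


class TestRleEncodeColumn:
    def test_worked_example(self):
        col = rle_encode_column(WORKED_COLUMN)
        assert col.p.tolist() == [1, 3, 4, 5, 9]
        assert col.uv.tolist() == [0, 2, 1, 3, 5]
        assert col.c == 15
        assert col.first_symbol == 0
        assert col.n_runs == 5

    def test_all_zeros(self):
        col = rle_encode_column(np.zeros(17, dtype=np.uint8))
        assert col.p.tolist() == [1] and col.uv.tolist() == [0]
        assert col.c == 17 and col.n_runs == 1

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            rle_encode_column(np.array([], dtype=np.uint8))

    @pytest.mark.parametrize("seed", range(25))
    def test_decode_inverts_encode_and_uv_counts(self, seed):
        bits = random_column(seed)
        col = rle_encode_column(bits)
        assert np.array_equal(col.decode(), bits)
        for k, head in enumerate(col.p):
            before = bits[: head - 1]
            opposite = 1 - col.run_symbol(k)
            assert col.uv[k] == int((before == opposite).sum())


class TestRankAndSymbol:
    def test_nothing_before_first_position(self):
        col = rle_encode_column(WORKED_COLUMN)
        assert rank_before(col, 1) == (0, 0)

    def test_worked_ranks(self):
        col = rle_encode_column(WORKED_COLUMN)
        assert rank_before(col, 9) == (3, 5)

    def test_symbols_from_printed_string(self):
        col = rle_encode_column(WORKED_COLUMN)
        assert [symbol_at(col, i) for i in (1, 5, 20)] == [0, 1, 0]
        assert [symbol_at(col, i) for i in range(1, 21)] == WORKED_COLUMN.tolist()

    @pytest.mark.parametrize("seed", range(10))
    def test_rank_identity_and_agreement_with_decode(self, seed):
        bits = random_column(seed)
        col = rle_encode_column(bits)
        for i in range(1, len(bits) + 2):
            u, v = rank_before(col, i)
            assert u + v == i - 1
            assert u == int((bits[: i - 1] == 0).sum())

    def test_out_of_range_rejected(self):
        col = rle_encode_column(WORKED_COLUMN)
        with pytest.raises(IndexError):
            rank_before(col, 0)
        with pytest.raises(IndexError):
            symbol_at(col, 21)


class TestThresholds:
    def test_singleton_run(self):
        heads = np.array([1, 4, 5])
        da = np.array([0, 1, 1, 2, 3])
        # run [4..4]: minimum of DA over [4..5] is at position 4
        assert compute_thresholds(da, heads, 5)[1] == 4

    def test_first_minimum_wins(self):
        # one run [1..4] followed by [5..5]; DA over [1..5] = [5,2,2,7,9]
        heads = np.array([1, 5])
        da = np.array([5, 2, 2, 7, 9])
        assert compute_thresholds(da, heads, 5)[0] == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_linear_scan(self, seed):
        rng = np.random.default_rng(seed)
        bits = random_column(seed, h=30)
        da = rng.integers(0, 8, 30)
        col = rle_encode_column(bits, da=da)
        for k, s in enumerate(col.p):
            e = col.run_end(k)
            window = list(range(s, min(e + 1, 30) + 1))
            best = min(window, key=lambda pos: (da[pos - 1], pos))
            assert col.thresholds[k] == best


class TestFlMap:
    def test_worked_column_embedded_in_identity_panel(self):
        # a 20x1 panel whose single PBWT column is the printed one
        panel = panel_io.HaplotypePanel(
            WORKED_COLUMN.reshape(-1, 1), [f"H{k}" for k in range(1, 21)]
        )
        index = build_index(panel)
        assert fl_map(index, 1, 1) == 1  # first zero maps to the first position
        assert fl_map(index, 1, 3) == 0 + 15 + 1  # first one maps past all zeros

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_fl_consistency_with_prefix_arrays(self, seed):
        panel, _ = random_instance(seed, h_range=(5, 25), w_range=(5, 25))
        index = build_index(panel)
        cw = pbwt_core.build_columnwise_pbwt(panel)
        for j in range(1, panel.n_sites + 1):
            images = [fl_map(index, j, i) for i in range(1, panel.n_haplotypes + 1)]
            # PA_{j+1}[fl(i,j)] = PA_j[i]: the same haplotype, one column on
            for i, img in enumerate(images, start=1):
                assert cw.pa(j + 1)[img - 1] == cw.pa(j)[i - 1]
            assert len(set(images)) == len(images)  # injective over the column
            for sym in (0, 1):
                sub = [
                    img for i, img in enumerate(images, start=1)
                    if symbol_at(index.columns[j - 1], i) == sym
                ]
                assert sub == sorted(sub)  # order-preserving within a symbol


class TestBuildIndex:
    def test_identical_rows_single_run_per_column(self):
        panel = panel_io.synth_panel(h=10, w=20, n_founders=1, switch_rate=0, mut_rate=0, seed=3)
        index = build_index(panel)
        assert all(col.n_runs == 1 for col in index.columns)
        assert index.r == 20

    def test_decodes_to_oracle_pbwt(self):
        panel = panel_io.synth_panel(h=20, w=25, n_founders=1, mut_rate=0.05, seed=3)
        index = build_index(panel)
        cw = pbwt_core.build_columnwise_pbwt(panel)
        for j in range(1, panel.n_sites + 1):
            assert np.array_equal(index.columns[j - 1].decode(), cw.col(j))

    def test_run_total_matches_oracle(self, mosaic_panel, mosaic_index):
        cw = pbwt_core.build_columnwise_pbwt(mosaic_panel)
        oracle_r = sum(
            len(rle_encode_column(cw.col(j)).p) for j in range(1, mosaic_panel.n_sites + 1)
        )
        assert mosaic_index.r == oracle_r

    def test_panel_access_reproduces_matrix(self, mosaic_panel, mosaic_index):
        for i in range(1, mosaic_panel.n_haplotypes + 1):
            for j in range(1, mosaic_panel.n_sites + 1):
                assert mosaic_index.panel_access(i, j) == mosaic_panel.alleles[i - 1, j - 1]

    @pytest.mark.parametrize("seed", range(8))
    def test_space_stays_within_run_budget(self, seed):
        panel, _ = random_instance(seed)
        index = build_index(panel)
        stats = index_stats(index)
        budget = stats["r"] + index.h + index.w
        assert stats["total_integers"] <= SPACE_CONSTANT * budget


class TestSerialization:
    def test_round_trip_every_field(self, mosaic_index, tmp_path):
        path = tmp_path / "x.mupbwt"
        serialize(mosaic_index, path)
        back = deserialize(path)
        assert (back.h, back.w, back.haplotype_ids) == (
            mosaic_index.h, mosaic_index.w, mosaic_index.haplotype_ids,
        )
        for a, b in zip(mosaic_index.columns, back.columns):
            assert a.c == b.c and a.first_symbol == b.first_symbol
            for f in ("p", "uv", "thresholds", "pa_start", "pa_end", "da_start"):
                assert np.array_equal(getattr(a, f), getattr(b, f))
        assert np.array_equal(back.sentinel_pa, mosaic_index.sentinel_pa)
        assert np.array_equal(back.sentinel_da, mosaic_index.sentinel_da)
        for a, b in zip(mosaic_index.panel_cols, back.panel_cols):
            assert np.array_equal(a.p, b.p) and a.first_symbol == b.first_symbol

    def test_truncated_file_rejected(self, mosaic_index, tmp_path):
        path = tmp_path / "x.mupbwt"
        serialize(mosaic_index, path)
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) // 2])
        with pytest.raises(SerializationError, match="truncated"):
            deserialize(path)

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "x.mupbwt"
        path.write_bytes(b"NOTMUP" + b"\x00" * 64)
        with pytest.raises(SerializationError, match="MUPBWT"):
            deserialize(path)

    def test_version_bump_rejected(self, mosaic_index, tmp_path, monkeypatch):
        path = tmp_path / "x.mupbwt"
        monkeypatch.setattr(rlpbwt_index, "FORMAT_VERSION", 99)
        serialize(mosaic_index, path)
        monkeypatch.undo()
        with pytest.raises(SerializationError, match="version 99"):
            deserialize(path)


class TestIndexStats:
    def test_identical_rows_mean_one_run(self):
        panel = panel_io.synth_panel(h=8, w=10, n_founders=1, switch_rate=0, mut_rate=0, seed=0)
        stats = index_stats(build_index(panel))
        assert stats["mean_runs_per_column"] == 1.0

    def test_internal_consistency(self, mosaic_index):
        stats = index_stats(mosaic_index)
        assert stats["total_integers"] == sum(stats["components"].values())
        assert stats["mean_runs_per_column"] == stats["r"] / stats["w"]
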