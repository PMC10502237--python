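"""The run-length compressed PBWT index (O(r + h + w) integers).

Each PBWT column is stored as its maximal runs only: run head positions,
an interleaved zero/one rank sample per run, the column's total zero
count, the first-run symbol, one threshold per run (the first position of
the minimum divergence value inside the run) and the prefix/divergence
arrays sampled at run boundaries.  Together with a run-length view of the
original panel columns and a fully sampled sentinel column, this is
everything needed to answer set-maximal exact match queries and locate
their occurrences without ever reconstructing the uncompressed PBWT.
"""

from __future__ import annotations

import io
import json
import struct
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Optional

import numpy as np

from .panel_io import HaplotypePanel
from .pbwt_core import iterate_pbwt

__all__ = [
    "RLEColumn",
    "PanelColumn",
    "MuPBWTIndex",
    "SerializationError",
    "rle_encode_column",
    "find_run",
    "rank_before",
    "symbol_at",
    "fl_map",
    "compute_thresholds",
    "build_index",
    "serialize",
    "deserialize",
    "index_stats",
]

MAGIC = b"MUPBWT"
FORMAT_VERSION = 1


class SerializationError(ValueError):
    """Raised for malformed, truncated or incompatible index files."""


@dataclass
class RLEColumn:
    """One PBWT column compressed to its runs.

    ``p[k]`` is the 1-based start of run k; ``uv[k]`` counts the
    opposite symbol strictly before ``p[k]`` (ones before a zero-run,
    zeros before a one-run); ``c`` is the column's total zero count and
    ``first_symbol`` the symbol of run 1 (runs alternate from there).
    ``thresholds[k]`` is the first position of the minimum divergence
    value within run k.  ``pa_start``/``pa_end`` sample the prefix array
    at each run's first/last position and ``da_start`` the divergence
    array at each run's first position.
    """

    h: int
    p: np.ndarray
    uv: np.ndarray
    c: int
    first_symbol: int
    thresholds: np.ndarray
    pa_start: np.ndarray
    pa_end: np.ndarray
    da_start: np.ndarray

    @property
    def n_runs(self) -> int:
        return len(self.p)

    def run_symbol(self, k: int) -> int:
        """Symbol of run k (0-based run index)."""
        return self.first_symbol ^ (k & 1)

    def run_end(self, k: int) -> int:
        """1-based last position of run k (0-based run index)."""
        return int(self.p[k + 1]) - 1 if k + 1 < self.n_runs else self.h

    def decode(self) -> np.ndarray:
        """Expand back to the explicit length-h binary column."""
        out = np.empty(self.h, dtype=np.uint8)
        for k in range(self.n_runs):
            out[int(self.p[k]) - 1 : self.run_end(k)] = self.run_symbol(k)
        return out


@dataclass
class PanelColumn:
    """Run-length view of one original panel column (no samples needed)."""

    h: int
    p: np.ndarray
    first_symbol: int

    def symbol_at(self, i: int) -> int:
        if not 1 <= i <= self.h:
            raise IndexError(f"position {i} out of range 1..{self.h}")
        k = bisect_right(self.p, i) - 1
        return self.first_symbol ^ (k & 1)

    @property
    def n_runs(self) -> int:
        return len(self.p)


def _run_heads(bits: np.ndarray) -> np.ndarray:
    """1-based start positions of the maximal runs of a binary array."""
    change = np.flatnonzero(bits[1:] != bits[:-1]) + 1
    return np.concatenate(([0], change)) + 1


def compute_thresholds(da: np.ndarray, heads: np.ndarray, h: int) -> np.ndarray:
    """Per run, the first position attaining the minimum divergence value.

    ``heads`` are the 1-based run starts; run k covers
    [heads[k] .. heads[k+1]-1] (the last run ends at h).  The minimum is
    taken over positions [s .. e+1], one past the run end (clamped at h):
    on a mismatch inside the run, the common suffix with the preceding
    run's last row is min(DA[s..i]) while that with the following run's
    first row is min(DA[i+1..e+1]), so the position of the overall first
    minimum over [s..e+1] is exactly the pivot deciding which neighbour
    wins — ranks before it jump back, ranks at or after it jump forward.
    """
    da = np.asarray(da)
    t = np.empty(len(heads), dtype=np.int64)
    for k, s in enumerate(heads):
        e = int(heads[k + 1]) - 1 if k + 1 < len(heads) else h
        seg = da[s - 1 : min(e + 1, h)]
        t[k] = s + int(np.argmin(seg))
    return t


def rle_encode_column(
    bits: np.ndarray,
    pa: Optional[np.ndarray] = None,
    da: Optional[np.ndarray] = None,
) -> RLEColumn:
    """Compress one PBWT column, sampling PA/DA at run boundaries.

    ``pa``/``da`` default to the identity permutation and all-zero
    divergence, which is only appropriate for standalone column encoding
    (e.g. inspecting the mapping structure of a single column).
    """
    bits = np.asarray(bits, dtype=np.uint8).ravel()
    h = bits.shape[0]
    if h == 0:
        raise ValueError("cannot encode an empty column")
    if pa is None:
        pa = np.arange(1, h + 1, dtype=np.int64)
    if da is None:
        da = np.zeros(h, dtype=np.int64)
    pa = np.asarray(pa)
    da = np.asarray(da)
    if len(pa) != h or len(da) != h:
        raise ValueError("pa/da length must match the column length")
    heads = _run_heads(bits)
    first_symbol = int(bits[0])
    # cumulative zero counts; uv[k] is the opposite-symbol rank at the head
    zeros_cum = np.concatenate(([0], np.cumsum(bits == 0)))
    uv = np.empty(len(heads), dtype=np.int64)
    for k, s in enumerate(heads):
        zeros_before = int(zeros_cum[s - 1])
        ones_before = (s - 1) - zeros_before
        uv[k] = ones_before if first_symbol ^ (k & 1) == 0 else zeros_before
    ends = np.concatenate((heads[1:] - 1, [h]))
    return RLEColumn(
        h=h,
        p=heads,
        uv=uv,
        c=int(zeros_cum[-1]),
        first_symbol=first_symbol,
        thresholds=compute_thresholds(da, heads, h),
        pa_start=pa[heads - 1].astype(np.int64),
        pa_end=pa[ends - 1].astype(np.int64),
        da_start=da[heads - 1].astype(np.int64),
    )


def find_run(col: RLEColumn, i: int) -> int:
    """0-based index of the run containing 1-based position ``i``."""
    if not 1 <= i <= col.h:
        raise IndexError(f"position {i} out of range 1..{col.h}")
    return bisect_right(col.p, i) - 1


def rank_before(col: RLEColumn, i: int) -> tuple[int, int]:
    """(zeros, ones) strictly before position ``i`` (1 <= i <= h+1).

    Computed from the run containing position i-1, its interleaved rank
    sample and offset arithmetic — the column is never decoded.
    """
    if not 1 <= i <= col.h + 1:
        raise IndexError(f"position {i} out of range 1..{col.h + 1}")
    if i == 1:
        return 0, 0
    k = bisect_right(col.p, i - 1) - 1
    head = int(col.p[k])
    inside = i - head  # symbols of this run strictly before i
    opp = int(col.uv[k])
    same = (head - 1) - opp + inside
    if col.run_symbol(k) == 0:
        return same, opp
    return opp, same


def symbol_at(col: RLEColumn, i: int) -> int:
    """Decoded symbol at position ``i`` via predecessor search on run heads."""
    return col.run_symbol(find_run(col, i))


@dataclass
class MuPBWTIndex:
    """The complete run-length compressed PBWT index of one panel."""

    h: int
    w: int
    haplotype_ids: list[str]
    columns: list[RLEColumn]
    sentinel_pa: np.ndarray
    sentinel_da: np.ndarray
    panel_cols: list[PanelColumn]
    phi: "object" = field(default=None, repr=False)  # PhiSupport, built on demand

    @property
    def r(self) -> int:
        """Total PBWT run count over all columns."""
        return sum(col.n_runs for col in self.columns)

    def panel_access(self, i: int, j: int) -> int:
        """Original matrix symbol M[i][j] (1-based row and column)."""
        if not 1 <= j <= self.w:
            raise IndexError(f"column {j} out of range 1..{self.w}")
        return self.panel_cols[j - 1].symbol_at(i)

    def pa_first(self, j: int) -> int:
        """PA_j[1] for 1 <= j <= w+1, from the first run's sample."""
        if j == self.w + 1:
            return int(self.sentinel_pa[0])
        return int(self.columns[j - 1].pa_start[0])


def fl_map(index: MuPBWTIndex, j: int, i: int) -> int:
    """Forward step: position in PA_{j+1} of the haplotype at rank i in PA_j.

    The mapping sends a zero at rank i to position u+1 (its zero-rank)
    and a one to position v + c + 1, where u/v count zeros/ones strictly
    before i and c is the column's zero total.
    """
    if not 1 <= j <= index.w:
        raise IndexError(f"column {j} out of range 1..{index.w}")
    col = index.columns[j - 1]
    u, v = rank_before(col, i)
    if symbol_at(col, i) == 0:
        return u + 1
    return v + col.c + 1


def build_index(panel: HaplotypePanel) -> MuPBWTIndex:
    """Build the compressed index in one streaming pass over the panel.

    The columnwise PBWT construction runs once; each uncompressed
    PA/DA/PBWT column is compressed and then discarded, so peak memory
    stays at one column plus the compressed output.
    """
    from .phi_locate import build_phi_support

    h, w = panel.n_haplotypes, panel.n_sites
    columns: list[RLEColumn] = []
    sentinel_pa = sentinel_da = None
    for j, pa, da, col in iterate_pbwt(panel):
        if col is None:
            sentinel_pa = pa.copy()
            sentinel_da = da.copy()
        else:
            columns.append(rle_encode_column(col, pa, da))
    panel_cols = []
    for j in range(w):
        bits = panel.alleles[:, j]
        panel_cols.append(PanelColumn(h=h, p=_run_heads(bits), first_symbol=int(bits[0])))
    index = MuPBWTIndex(
        h=h,
        w=w,
        haplotype_ids=list(panel.haplotype_ids),
        columns=columns,
        sentinel_pa=sentinel_pa,
        sentinel_da=sentinel_da,
        panel_cols=panel_cols,
    )
    index.phi = build_phi_support(index)
    return index


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------
#
# Little-endian binary format:
#   magic "MUPBWT" | uint16 version | uint64 h | uint64 w | uint64 r
#   | length-prefixed JSON haplotype id blob
#   | arrays in a fixed schema order, each as:
#       uint8 byte-width (1/2/4/8) | uint64 count | payload
# The byte width of each array is the minimal width covering its maximum.
# The Phi support tables are derived data and are rebuilt on load.

_WIDTH_DTYPE = {1: "<u1", 2: "<u2", 4: "<u4", 8: "<u8"}


def _write_array(fh: BinaryIO, arr: np.ndarray) -> None:
    arr = np.asarray(arr, dtype=np.int64)
    if arr.size and int(arr.min()) < 0:
        raise SerializationError("negative value in index array")
    mx = int(arr.max()) if arr.size else 0
    width = next(wd for wd in (1, 2, 4, 8) if mx < (1 << (8 * wd)))
    fh.write(struct.pack("<BQ", width, arr.size))
    fh.write(arr.astype(_WIDTH_DTYPE[width]).tobytes())


def _read_exact(fh: BinaryIO, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise SerializationError("truncated index file")
    return data


def _read_array(fh: BinaryIO) -> np.ndarray:
    width, count = struct.unpack("<BQ", _read_exact(fh, 9))
    if width not in _WIDTH_DTYPE:
        raise SerializationError(f"invalid array byte width {width}")
    raw = _read_exact(fh, width * count)
    return np.frombuffer(raw, dtype=_WIDTH_DTYPE[width]).astype(np.int64)


def serialize(index: MuPBWTIndex, path: str | Path) -> None:
    """Write the index to a binary file (Phi tables are rebuilt on load)."""
    buf = io.BytesIO()
    buf.write(MAGIC)
    buf.write(struct.pack("<HQQQ", FORMAT_VERSION, index.h, index.w, index.r))
    ids_blob = json.dumps(index.haplotype_ids).encode()
    buf.write(struct.pack("<Q", len(ids_blob)))
    buf.write(ids_blob)
    for col in index.columns:
        _write_array(buf, col.p)
        _write_array(buf, col.uv)
        _write_array(buf, np.array([col.c, col.first_symbol]))
        _write_array(buf, col.thresholds)
        _write_array(buf, col.pa_start)
        _write_array(buf, col.pa_end)
        _write_array(buf, col.da_start)
    _write_array(buf, index.sentinel_pa)
    _write_array(buf, index.sentinel_da)
    for pc in index.panel_cols:
        _write_array(buf, pc.p)
        _write_array(buf, np.array([pc.first_symbol]))
    Path(path).write_bytes(buf.getvalue())


def deserialize(path: str | Path) -> MuPBWTIndex:
    """Read an index written by :func:`serialize`; rejects bad magic/version."""
    from .phi_locate import build_phi_support

    with open(path, "rb") as fh:
        magic = _read_exact(fh, len(MAGIC))
        if magic != MAGIC:
            raise SerializationError(
                f"bad magic {magic!r}, expected {MAGIC!r}: not a mupbwt index"
            )
        version, h, w, r = struct.unpack("<HQQQ", _read_exact(fh, 26))
        if version != FORMAT_VERSION:
            raise SerializationError(
                f"unsupported format version {version}, expected {FORMAT_VERSION}"
            )
        (n_ids,) = struct.unpack("<Q", _read_exact(fh, 8))
        haplotype_ids = json.loads(_read_exact(fh, n_ids).decode())
        columns = []
        for _ in range(w):
            p = _read_array(fh)
            uv = _read_array(fh)
            c, first_symbol = (int(x) for x in _read_array(fh))
            thresholds = _read_array(fh)
            pa_start = _read_array(fh)
            pa_end = _read_array(fh)
            da_start = _read_array(fh)
            columns.append(
                RLEColumn(
                    h=h,
                    p=p,
                    uv=uv,
                    c=c,
                    first_symbol=first_symbol,
                    thresholds=thresholds,
                    pa_start=pa_start,
                    pa_end=pa_end,
                    da_start=da_start,
                )
            )
        sentinel_pa = _read_array(fh)
        sentinel_da = _read_array(fh)
        panel_cols = []
        for _ in range(w):
            p = _read_array(fh)
            (first_symbol,) = (int(x) for x in _read_array(fh))
            panel_cols.append(PanelColumn(h=h, p=p, first_symbol=first_symbol))
    index = MuPBWTIndex(
        h=h,
        w=w,
        haplotype_ids=haplotype_ids,
        columns=columns,
        sentinel_pa=sentinel_pa,
        sentinel_da=sentinel_da,
        panel_cols=panel_cols,
    )
    if index.r != r:
        raise SerializationError("run-count header does not match column data")
    index.phi = build_phi_support(index)
    return index


def index_stats(index: MuPBWTIndex) -> dict:
    """Size summary: dimensions, run counts and stored integers per component."""
    runs = [col.n_runs for col in index.columns]
    r = sum(runs)
    mapping = sum(2 * col.n_runs + 2 for col in index.columns)  # p, uv, c, b
    samples = sum(3 * col.n_runs for col in index.columns)  # pa_start/pa_end/da_start
    thresholds = r
    sentinel = 2 * index.h
    panel_access = sum(pc.n_runs + 1 for pc in index.panel_cols)
    phi = index.phi.n_integers if index.phi is not None else 0
    components = {
        "mapping": mapping,
        "samples": samples,
        "thresholds": thresholds,
        "sentinel": sentinel,
        "panel_access": panel_access,
        "phi": phi,
    }
    return {
        "h": index.h,
        "w": index.w,
        "r": r,
        "mean_runs_per_column": r / index.w,
        "max_runs_per_column": max(runs),
        "components": components,
        "total_integers": sum(components.values()),
    }
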