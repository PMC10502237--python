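"""Phi queries, divergence recovery from samples, and SMEM locating.

The Phi function at column j maps a prefix-array value y to the value
immediately above it in PA_j (its co-lexicographic predecessor up to
column j-1); Phi-inverse maps to the value below.  Because the forward
(FL) mapping of two adjacent equal symbols keeps the pair adjacent in the
next column, the predecessor of y is unchanged from column j until the
first column k >= j where y sits at a run start — and there it is stored
as the PA sample ending the preceding run.  Phi therefore reduces to a
successor search over the columns where y touches a run boundary, exactly
the r-index strategy transplanted to the PBWT.

Divergence values are recovered the same way: if y heads a run at column
k >= j, the sampled DA grows by one per intervening column, so
``DA_j = DA_k - (k - j)``.  Locating all occurrences of an SMEM then
walks Phi / Phi-inverse outward from the matched row while the recovered
divergence stays at least the match length.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .rlpbwt_index import MuPBWTIndex, find_run, fl_map

__all__ = [
    "PhiSupport",
    "build_phi_support",
    "phi",
    "phi_inv",
    "recover_da",
    "iterated_fl_phi",
    "pa_position",
    "expand_occurrences",
    "locate_smem",
]

_NO_NEIGHBOR = 0  # stored sentinel: y is at the very top/bottom of the column


@dataclass
class PhiSupport:
    """Per-value boundary samples answering Phi / Phi-inverse by successor search.

    For each haplotype value y (1..h), ``start_cols[y-1]`` lists, sorted,
    the columns where y sits at a run start (the sentinel column w+1 is
    included for every y since every position is a boundary there);
    ``start_neighbors`` gives the predecessor of y in PA at each such
    column (0 when y is at the top) and ``start_da`` the divergence
    sample at y's position.  ``end_cols``/``end_neighbors`` mirror this
    at run ends, giving successors.
    """

    start_cols: list[np.ndarray]
    start_neighbors: list[np.ndarray]
    start_da: list[np.ndarray]
    end_cols: list[np.ndarray]
    end_neighbors: list[np.ndarray]

    @property
    def n_integers(self) -> int:
        return sum(
            arr.size
            for group in (
                self.start_cols,
                self.start_neighbors,
                self.start_da,
                self.end_cols,
                self.end_neighbors,
            )
            for arr in group
        )


def build_phi_support(index: MuPBWTIndex) -> PhiSupport:
    """Collect run-boundary PA/DA samples per haplotype value."""
    h, w = index.h, index.w
    sc: list[list[int]] = [[] for _ in range(h)]
    sn: list[list[int]] = [[] for _ in range(h)]
    sd: list[list[int]] = [[] for _ in range(h)]
    ec: list[list[int]] = [[] for _ in range(h)]
    en: list[list[int]] = [[] for _ in range(h)]
    for j, col in enumerate(index.columns, start=1):
        r = col.n_runs
        for k in range(r):
            ys = int(col.pa_start[k])
            sc[ys - 1].append(j)
            sn[ys - 1].append(int(col.pa_end[k - 1]) if k > 0 else _NO_NEIGHBOR)
            sd[ys - 1].append(int(col.da_start[k]))
            ye = int(col.pa_end[k])
            ec[ye - 1].append(j)
            en[ye - 1].append(int(col.pa_start[k + 1]) if k + 1 < r else _NO_NEIGHBOR)
    spa, sda = index.sentinel_pa, index.sentinel_da
    for i in range(h):
        y = int(spa[i])
        sc[y - 1].append(w + 1)
        sn[y - 1].append(int(spa[i - 1]) if i > 0 else _NO_NEIGHBOR)
        sd[y - 1].append(int(sda[i]))
        ec[y - 1].append(w + 1)
        en[y - 1].append(int(spa[i + 1]) if i + 1 < h else _NO_NEIGHBOR)
    to_arr = lambda lists: [np.array(v, dtype=np.int64) for v in lists]
    return PhiSupport(
        start_cols=to_arr(sc),
        start_neighbors=to_arr(sn),
        start_da=to_arr(sd),
        end_cols=to_arr(ec),
        end_neighbors=to_arr(en),
    )


def _check_query(index: MuPBWTIndex, j: int, y: int) -> None:
    if not 1 <= j <= index.w + 1:
        raise IndexError(f"column {j} out of range 1..{index.w + 1}")
    if not 1 <= y <= index.h:
        raise ValueError(f"prefix-array value {y} out of range 1..{index.h}")


def _successor_sample(cols: np.ndarray, j: int) -> int:
    """Index of the first sampled column >= j (the sentinel guarantees one)."""
    return bisect_left(cols, j)


def phi(index: MuPBWTIndex, j: int, y: int) -> Optional[int]:
    """Predecessor of value ``y`` in PA_j, or None when y is at the top."""
    _check_query(index, j, y)
    sup: PhiSupport = index.phi
    cols = sup.start_cols[y - 1]
    k = _successor_sample(cols, j)
    nb = int(sup.start_neighbors[y - 1][k])
    return None if nb == _NO_NEIGHBOR else nb


def phi_inv(index: MuPBWTIndex, j: int, y: int) -> Optional[int]:
    """Successor of value ``y`` in PA_j, or None when y is at the bottom."""
    _check_query(index, j, y)
    sup: PhiSupport = index.phi
    cols = sup.end_cols[y - 1]
    k = _successor_sample(cols, j)
    nb = int(sup.end_neighbors[y - 1][k])
    return None if nb == _NO_NEIGHBOR else nb


def recover_da(index: MuPBWTIndex, j: int, y: int) -> int:
    """Divergence of value ``y`` at column j, from the nearest start sample.

    If y first heads a run at sampled column k >= j, the divergence grew
    by exactly one per intervening column, so DA_j = DA_k - (k - j).
    Undefined (raises) when y is at the top of PA_j: the divergence is a
    comparison against the row above.
    """
    _check_query(index, j, y)
    sup: PhiSupport = index.phi
    cols = sup.start_cols[y - 1]
    k = _successor_sample(cols, j)
    if int(sup.start_neighbors[y - 1][k]) == _NO_NEIGHBOR:
        raise ValueError(f"value {y} is at the top of PA_{j}: divergence undefined")
    sampled_col = int(cols[k])
    return int(sup.start_da[y - 1][k]) - (sampled_col - j)


def pa_position(index: MuPBWTIndex, j: int, y: int) -> int:
    """Rank of haplotype ``y`` in PA_j, by forward-stepping from column 1."""
    _check_query(index, j, y)
    i = y  # PA_1 is the identity
    for t in range(1, j):
        i = fl_map(index, t, i)
    return i


def iterated_fl_phi(index: MuPBWTIndex, j: int, y: int) -> Optional[int]:
    """Phi by explicit FL walking — the reference route for cross-validation.

    Starting at y's rank in PA_j, step forward column by column while y
    is strictly inside a run (the pair above/below keeps equal symbols,
    so adjacency is preserved); at the first column where y heads a run
    the predecessor is the sample ending the preceding run.  Terminates
    within w+1-j steps because the sentinel column is all boundaries.
    """
    _check_query(index, j, y)
    i = pa_position(index, j, y)
    t = j
    while t <= index.w:
        col = index.columns[t - 1]
        k = find_run(col, i)
        if i == int(col.p[k]):  # y heads run k: the symbols above/below differ
            return int(col.pa_end[k - 1]) if k > 0 else None
        i = fl_map(index, t, i)
        t += 1
    return int(index.sentinel_pa[i - 2]) if i > 1 else None


def expand_occurrences(
    pa: Sequence[int], da: Sequence[int], seed_value: int, length: int
) -> list[int]:
    """Occurrence block around ``seed_value`` on explicit PA/DA arrays.

    The uncompressed counterpart of :func:`locate_smem`: all rows sharing
    a length-``length`` suffix with the seed form a contiguous block in
    the prefix array, delimited by the first divergence value below
    ``length`` in each direction.  Returns the rows in ascending order.
    """
    pa = np.asarray(pa)
    da = np.asarray(da)
    (i,) = np.flatnonzero(pa == seed_value)
    occ = [int(seed_value)]
    k = i
    while k > 0 and da[k] >= length:
        k -= 1
        occ.append(int(pa[k]))
    k = i
    while k + 1 < len(pa) and da[k + 1] >= length:
        k += 1
        occ.append(int(pa[k]))
    return sorted(occ)


def locate_smem(
    index: MuPBWTIndex,
    ms,
    smem: tuple[int, int],
) -> list[int]:
    """All panel rows sharing one SMEM, by Phi expansion from the matched row.

    The SMEM (start, length) must have been extracted from ``ms`` (its
    end column k must satisfy ``ms.len[k] == length``).  All sharing rows
    are consecutive in PA_{k+1}; starting from the matched row the walk
    adds predecessors while the recovered divergence at the current row
    stays >= length, and successors while the divergence at the successor
    row does.  Rows are returned in ascending panel order.
    """
    start, length = smem
    k = start + length - 1
    if not 1 <= k <= index.w:
        raise ValueError(f"SMEM end column {k} out of range 1..{index.w}")
    if int(ms.len[k - 1]) != length or length < 1:
        raise ValueError(
            f"SMEM (start={start}, length={length}) is inconsistent with the "
            f"matching statistics (len[{k}] = {int(ms.len[k - 1])})"
        )
    q = k + 1  # adjacency column: co-lexicographic order up to column k
    seed = int(ms.row[k - 1])
    occ = [seed]
    cur = seed
    while True:  # upward: predecessors share while DA at cur >= length
        pred = phi(index, q, cur)
        if pred is None or recover_da(index, q, cur) < length:
            break
        occ.append(pred)
        cur = pred
    cur = seed
    while True:  # downward: successor shares while DA at successor >= length
        succ = phi_inv(index, q, cur)
        if succ is None or recover_da(index, q, succ) < length:
            break
        occ.append(succ)
        cur = succ
    return sorted(occ)
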