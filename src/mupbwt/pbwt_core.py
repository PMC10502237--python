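"""Uncompressed positional Burrows-Wheeler transform and brute-force oracles.

The PBWT of an ``h x w`` binary panel M reorders, at every column j, the
rows of M by the co-lexicographic order of their length-(j-1) prefixes.
Three families of arrays describe it:

* prefix arrays ``PA_j`` — the permutation of row indices 1..h at column j;
* divergence arrays ``DA_j`` — at rank i, the length of the longest common
  suffix of the (j-1)-prefixes of rows ``PA_j[i]`` and ``PA_j[i-1]``;
* PBWT columns — column j of M permuted by ``PA_j``.

Everything here is deliberately uncompressed and simple (O(h*w) space):
this module is the ground truth that every compressed operation in the
rest of the package is validated against.  Indices are 1-based throughout,
matching the standard formulation; the arrays are stored 0-offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .panel_io import HaplotypePanel, QueryPattern

__all__ = [
    "ColumnwisePBWT",
    "iterate_pbwt",
    "build_columnwise_pbwt",
    "lcs_len",
    "suffix_match_lengths",
    "naive_matching_statistics",
    "naive_smems",
    "naive_occurrences",
    "pa_predecessor",
    "pa_successor",
    "naive_phi",
    "naive_phi_inv",
]


@dataclass
class ColumnwisePBWT:
    """All prefix arrays, divergence arrays and PBWT columns of a panel.

    ``PA`` and ``DA`` hold w+1 arrays (for j = 1 .. w+1, the last being
    the sentinel ordering by all w columns); ``pbwt_cols`` holds the w
    permuted panel columns.  Access with the 1-based helpers ``pa``,
    ``da`` and ``col``.
    """

    h: int
    w: int
    PA: list[np.ndarray]
    DA: list[np.ndarray]
    pbwt_cols: list[np.ndarray]

    def pa(self, j: int) -> np.ndarray:
        """Prefix array at column j (1 <= j <= w+1); values are rows 1..h."""
        if not 1 <= j <= self.w + 1:
            raise IndexError(f"column {j} out of range 1..{self.w + 1}")
        return self.PA[j - 1]

    def da(self, j: int) -> np.ndarray:
        if not 1 <= j <= self.w + 1:
            raise IndexError(f"column {j} out of range 1..{self.w + 1}")
        return self.DA[j - 1]

    def col(self, j: int) -> np.ndarray:
        """PBWT column j (1 <= j <= w): panel column j permuted by PA_j."""
        if not 1 <= j <= self.w:
            raise IndexError(f"column {j} out of range 1..{self.w}")
        return self.pbwt_cols[j - 1]


def iterate_pbwt(
    panel: HaplotypePanel,
) -> Iterator[tuple[int, np.ndarray, np.ndarray, Optional[np.ndarray]]]:
    """Stream ``(j, PA_j, DA_j, col(PBWT)_j)`` for j = 1 .. w+1.

    The sentinel column j = w+1 (ordering by all w columns) is yielded
    last with ``None`` in place of a PBWT column.  PA_{j+1}/DA_{j+1} are
    derived from PA_j/DA_j by the single-pass stable split on the current
    PBWT column (Durbin's update), tracking suffix lengths directly.
    """
    h, w = panel.n_haplotypes, panel.n_sites
    alleles = panel.alleles
    pa = np.arange(1, h + 1, dtype=np.int64)
    da = np.zeros(h, dtype=np.int64)
    for j in range(1, w + 1):
        col = alleles[pa - 1, j - 1].astype(np.uint8)
        yield j, pa, da, col
        # split rows on the current symbol, keeping order; a row's new
        # divergence is the minimum suffix length seen since the previous
        # row that fell in the same symbol class, extended by one column.
        start = j - da  # first column of the common suffix with the row above
        p = q = j + 1  # sentinel: no common suffix yet
        a: list[int] = []
        b: list[int] = []
        d: list[int] = []
        e: list[int] = []
        for i in range(h):
            s = start[i]
            if s > p:
                p = s
            if s > q:
                q = s
            if col[i] == 0:
                a.append(pa[i])
                d.append(p)
                p = 0
            else:
                b.append(pa[i])
                e.append(q)
                q = 0
        pa = np.array(a + b, dtype=np.int64)
        da = (j + 1) - np.array(d + e, dtype=np.int64)
    yield w + 1, pa, da, None


def build_columnwise_pbwt(panel: HaplotypePanel) -> ColumnwisePBWT:
    """Materialize every PA_j, DA_j and PBWT column, including the sentinel."""
    PA: list[np.ndarray] = []
    DA: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for j, pa, da, col in iterate_pbwt(panel):
        PA.append(pa)
        DA.append(da)
        if col is not None:
            cols.append(col)
    return ColumnwisePBWT(panel.n_haplotypes, panel.n_sites, PA, DA, cols)


def lcs_len(a: Sequence, b: Sequence) -> int:
    """Length of the longest common suffix of two sequences."""
    n = 0
    for x, y in zip(reversed(a), reversed(b)):
        if x != y:
            break
        n += 1
    return n


def suffix_match_lengths(panel: HaplotypePanel, pattern: QueryPattern) -> np.ndarray:
    """``(h, w)`` matrix L with L[k-1, j-1] = lcs(P[1..j], S_k[1..j]).

    The direct dynamic program over the match matrix: L is 1 + the value
    to the left wherever pattern and panel agree, else 0.
    """
    if len(pattern) != panel.n_sites:
        raise ValueError(
            f"pattern length {len(pattern)} != panel width {panel.n_sites}"
        )
    eq = panel.alleles == pattern.alleles[np.newaxis, :]
    L = np.zeros(eq.shape, dtype=np.int64)
    L[:, 0] = eq[:, 0]
    for j in range(1, eq.shape[1]):
        L[:, j] = np.where(eq[:, j], L[:, j - 1] + 1, 0)
    return L


def naive_matching_statistics(panel: HaplotypePanel, pattern: QueryPattern):
    """Matching statistics by exhaustive scan over all rows and positions.

    For every j, ``len[j]`` is the longest suffix of P[1..j] shared with
    the j-prefix of any panel row, and ``row[j]`` is a row attaining it.
    Returns a :class:`~mupbwt.smem_query.MatchingStatistics` with ``pos``
    unset (the co-lexicographic rank is an index-internal notion).
    """
    from .smem_query import MatchingStatistics

    L = suffix_match_lengths(panel, pattern)
    lens = L.max(axis=0)
    rows = L.argmax(axis=0) + 1  # 1-based row attaining the maximum
    return MatchingStatistics(row=rows, len=lens, pos=None)


def naive_smems(
    panel: HaplotypePanel, pattern: QueryPattern, min_len: int = 1
) -> list[tuple[int, int]]:
    """All set-maximal exact matches by exhaustive substring search.

    A substring P[i..j] is an SMEM when it occurs in some panel row at
    the same columns and neither P[i-1..j] nor P[i..j+1] occurs (with the
    boundary cases at i=1 / j=w).  Returned as sorted (start, length)
    pairs, 1-based.
    """
    L = suffix_match_lengths(panel, pattern)
    w = panel.n_sites

    def occurs(i: int, j: int) -> bool:
        # P[i..j] occurs iff some row matches a suffix of length >= j-i+1 at j
        return bool((L[:, j - 1] >= j - i + 1).any())

    out = []
    for j in range(1, w + 1):
        for i in range(1, j + 1):
            if j - i + 1 < min_len:
                continue
            if not occurs(i, j):
                continue
            if (i == 1 or not occurs(i - 1, j)) and (j == w or not occurs(i, j + 1)):
                out.append((i, j - i + 1))
    return sorted(set(out))


def naive_occurrences(
    panel: HaplotypePanel, pattern: QueryPattern, start: int, length: int
) -> list[int]:
    """1-based panel rows where P[start..start+length-1] occurs, by direct scan."""
    end = start + length - 1
    L = suffix_match_lengths(panel, pattern)
    return (np.flatnonzero(L[:, end - 1] >= length) + 1).tolist()


# ---------------------------------------------------------------------------
# Phi on explicit prefix arrays
# ---------------------------------------------------------------------------

def pa_predecessor(pa: Sequence[int], y: int) -> Optional[int]:
    """Value immediately above ``y`` in a prefix array column, or None at the top."""
    pa = np.asarray(pa)
    h = pa.shape[0]
    if not 1 <= y <= h:
        raise ValueError(f"value {y} out of range 1..{h}")
    (i,) = np.flatnonzero(pa == y)
    return None if i == 0 else int(pa[i - 1])


def pa_successor(pa: Sequence[int], y: int) -> Optional[int]:
    """Value immediately below ``y`` in a prefix array column, or None at the bottom."""
    pa = np.asarray(pa)
    h = pa.shape[0]
    if not 1 <= y <= h:
        raise ValueError(f"value {y} out of range 1..{h}")
    (i,) = np.flatnonzero(pa == y)
    return None if i == h - 1 else int(pa[i + 1])


def naive_phi(cwpbwt: ColumnwisePBWT, j: int, y: int) -> Optional[int]:
    """Predecessor of value ``y`` in PA_j, read from the materialized array."""
    return pa_predecessor(cwpbwt.pa(j), y)


def naive_phi_inv(cwpbwt: ColumnwisePBWT, j: int, y: int) -> Optional[int]:
    """Successor of value ``y`` in PA_j, read from the materialized array."""
    return pa_successor(cwpbwt.pa(j), y)
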