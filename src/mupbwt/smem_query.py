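"""Matching statistics against the compressed index and SMEM extraction.

Matching statistics of a pattern P[1..w] against the panel are, per
column j, the length of the longest suffix of P[1..j] shared with the
j-prefix of any panel row (``len``) and a row attaining it (``row``).
They are computed in two passes: a forward pass navigates the compressed
PBWT with the FL mapping, using the per-run thresholds to pick the better
neighbouring run on a mismatch; a backward pass fills in the lengths by
direct symbol comparison through the compressed panel view.  Every SMEM
is then read off the statistics in a single right-to-left scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .panel_io import QueryPattern
from .rlpbwt_index import MuPBWTIndex, find_run, fl_map, symbol_at

__all__ = ["MatchingStatistics", "matching_statistics", "extract_smems"]


@dataclass
class MatchingStatistics:
    """Per-column (row, len) matching statistics of one query.

    ``row[j-1]`` is a 1-based panel row whose j-prefix shares the longest
    suffix with P[1..j]; ``len[j-1]`` is that length.  ``pos[j-1]``, when
    present, is the co-lexicographic rank of the matched haplotype in
    PA_{j+1}, the anchor used for locating; the brute-force oracle leaves
    it unset.
    """

    row: np.ndarray
    len: np.ndarray
    pos: Optional[np.ndarray] = None

    @property
    def w(self) -> int:
        return len(self.row)


def matching_statistics(index: MuPBWTIndex, pattern: QueryPattern) -> MatchingStatistics:
    """Two-pass matching statistics of ``pattern`` against the indexed panel.

    Forward pass: maintain (i, p) = (rank in the current PBWT column, the
    corresponding panel row).  On a match the row survives and i steps
    forward with the FL mapping.  On a mismatch inside run [s..e] the
    best extension is either the end of the preceding run or the start of
    the following one (both carry the query symbol); the run's threshold
    — the first minimum-divergence position — decides: ranks before the
    threshold bind tighter upward, so i < t takes the preceding run, else
    the following.  If the whole column is a single run of the wrong
    symbol no row matches here at all; matching restarts from the top of
    the next column.  Backward pass: lengths by longest-common-suffix
    comparison against the matched rows through the compressed panel
    view, reusing the previous comparison when the row repeats.
    """
    w, h = index.w, index.h
    if len(pattern) != w:
        raise ValueError(f"pattern length {len(pattern)} != index width {w}")
    P = pattern.alleles
    rows = np.empty(w, dtype=np.int64)
    poss = np.empty(w, dtype=np.int64)
    i, p = 1, 1  # PA_1 is the identity; all empty prefixes tie
    for k in range(1, w + 1):
        col = index.columns[k - 1]
        sym = int(P[k - 1])
        if col.n_runs == 1 and col.first_symbol != sym:
            # degenerate: the query symbol does not occur in this column
            i, p = 1, index.pa_first(k + 1)
        elif symbol_at(col, i) == sym:
            i = fl_map(index, k, i)
        else:
            kr = find_run(col, i)
            s, e = int(col.p[kr]), col.run_end(kr)
            if s == 1:
                take_prev = False
            elif e == h:
                take_prev = True
            else:
                take_prev = i < int(col.thresholds[kr])
            if take_prev:
                p = int(col.pa_end[kr - 1])
                i = fl_map(index, k, s - 1)
            else:
                p = int(col.pa_start[kr + 1])
                i = fl_map(index, k, e + 1)
        rows[k - 1] = p
        poss[k - 1] = i
    lens = np.zeros(w, dtype=np.int64)
    for k in range(w, 0, -1):
        q = int(rows[k - 1])
        if k < w and q == int(rows[k]) and lens[k] > 0:
            # the comparison for column k+1 already crossed column k
            lens[k - 1] = lens[k] - 1
        else:
            m = 0
            while m < k and index.panel_access(q, k - m) == int(P[k - m - 1]):
                m += 1
            lens[k - 1] = m
    return MatchingStatistics(row=rows, len=lens, pos=poss)


def extract_smems(ms: MatchingStatistics, min_len: int = 1) -> list[tuple[int, int]]:
    """Read the SMEMs out of matching statistics.

    Scanning j from w down to 1, position j ends an SMEM of length
    ``len[j]`` exactly when the match cannot be extended one column to
    the right, i.e. j = w or ``len[j] >= len[j+1]``.  Matches shorter
    than ``min_len`` (and all zero-length statistics) are dropped.
    Returns sorted, de-duplicated (start, length) pairs, 1-based.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    w = ms.w
    out = set()
    for j in range(w, 0, -1):
        lj = int(ms.len[j - 1])
        if lj < min_len:
            continue
        if j == w or lj >= int(ms.len[j]):
            out.add((j - lj + 1, lj))
    return sorted(out)
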