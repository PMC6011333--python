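"""Pairwise identity for short, near-equal-length amplicon sequences.

Global alignment with free end gaps under the scoring match +1, mismatch 0,
gap −1.  End gaps (a leading or trailing run of gaps in one sequence) cost
nothing but still count as alignment columns.  Among alignments of maximal
score the one with the most matches wins, then the one with the fewest
columns; identity is matches / columns of that alignment.  The deterministic
tie-break makes clustering and classification decisions exactly reproducible
and checkable against exhaustive enumeration.

The DP maximizes a single integer key encoding (score, matches, −columns)
lexicographically and is vectorized per row: the in-row gap recurrence
``cur[j] = max(x[j], cur[j-1] + g)`` is a running maximum of ``x[j] - j*g``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AlignmentStats:
    score: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 1.0


def align_stats(a: str, b: str) -> AlignmentStats:
    """Best (score, matches, −columns) end-gap-free alignment of a vs b."""
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return AlignmentStats(0, 0, max(n, m))
    A = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    B = np.frombuffer(b.encode("ascii"), dtype=np.uint8)

    cmax = n + m
    off_s = n + m  # score offset so keys stay non-negative
    K1 = min(n, m) + 1  # matches radix
    K2 = cmax + 1  # columns radix
    DIAG_MATCH = K1 * K2 + K2 - 1  # score+1, matches+1, columns+1
    DIAG_MISS = -1  # score+0, columns+1
    GAP = -(K1 * K2) - 1  # score-1, columns+1

    j_idx = np.arange(m + 1, dtype=np.int64)
    base = off_s * K1 * K2  # key of (score=0, matches=0, columns=0)
    prev = base + (cmax - j_idx)  # row 0: free leading gaps in a
    jg = j_idx * GAP
    last_col = np.empty(n + 1, dtype=np.int64)
    last_col[0] = prev[m]
    for i in range(1, n + 1):
        match = B == A[i - 1]
        diag = prev[:-1] + np.where(match, DIAG_MATCH, DIAG_MISS)
        up = prev[1:] + GAP
        du = np.maximum(diag, up)
        x = np.empty(m + 1, dtype=np.int64)
        x[0] = base + (cmax - i)  # column 0: free leading gaps in b
        x[1:] = du
        cur = np.maximum.accumulate(x - jg) + jg
        last_col[i] = cur[m]
        prev = cur

    # free trailing end gaps: only the column count grows
    i_idx = np.arange(n + 1, dtype=np.int64)
    best = int(max((prev - (m - j_idx)).max(), (last_col - (n - i_idx)).max()))

    columns = cmax - best % K2
    rest = best // K2
    matches = rest % K1
    score = rest // K1 - off_s
    return AlignmentStats(int(score), int(matches), int(columns))


def identity(a: str, b: str) -> float:
    """Fractional identity of the best end-gap-free alignment."""
    if a == b:
        return 1.0
    return align_stats(a, b).identity
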