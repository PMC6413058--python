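"""Independent local-alignment oracle for cross-checking the DP kernels.

Deliberately written with a different recurrence organization than the
package: full score matrices are built row by row with the linear-gap left
moves resolved by a max-plus prefix scan, and the greedy declumping loop
re-runs this matrix after masking. Shares only the tie-break policy
(smallest subject end, then query end; diagonal > up > left in traceback),
which is part of the contract being checked.
"""

from __future__ import annotations

import numpy as np

_CODE = {b: i for i, b in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, 4) for b in seq.upper()], dtype=np.int8)


def _substitution(q: np.ndarray, s: np.ndarray, match: int, mismatch: int
                  ) -> np.ndarray:
    eq = (q[:, None] == s[None, :]) & (q[:, None] < 4)
    return np.where(eq, match, mismatch)


def _segments(masked: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of unmasked subject positions."""
    segs = []
    start = None
    for j, m in enumerate(masked):
        if not m and start is None:
            start = j
        elif m and start is not None:
            segs.append((start, j))
            start = None
    if start is not None:
        segs.append((start, len(masked)))
    return segs


def sw_matrix(query: str, subject: str, match: int = 5, mismatch: int = -4,
              gap: int = 8, masked: np.ndarray | None = None) -> np.ndarray:
    """Full Smith-Waterman score matrix, linear gap, masked columns zero."""
    q = _encode(query)
    s = _encode(subject)
    n, m = q.size, s.size
    if masked is None:
        masked = np.zeros(m, dtype=bool)
    sub = _substitution(q, s, match, mismatch)
    segs = _segments(masked)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        prev, cur = H[i - 1], H[i]
        for a, b in segs:
            diag = prev[a:b] + sub[i - 1, a:b]
            up = prev[a + 1:b + 1] - gap
            best_non_left = np.maximum(np.maximum(diag, up), 0)
            # left-move chains within the segment via max-plus prefix scan
            idx = np.arange(b - a)
            cur[a + 1:b + 1] = np.maximum.accumulate(
                best_non_left + gap * idx) - gap * idx
    return H


def best_cell(H: np.ndarray) -> tuple[int, int, int]:
    """(score, i, j) of the maximum; ties -> smallest j, then smallest i."""
    score = int(H.max())
    cells = np.argwhere(H == score)
    order = np.lexsort((cells[:, 0], cells[:, 1]))
    i, j = cells[order[0]]
    return score, int(i), int(j)


def traceback_start(H, query, subject, match, mismatch, gap, bi, bj
                    ) -> tuple[int, int]:
    q = _encode(query)
    s = _encode(subject)
    i, j = bi, bj
    while H[i, j] > 0:
        sub = match if (q[i - 1] == s[j - 1] and q[i - 1] < 4) else mismatch
        if H[i, j] == H[i - 1, j - 1] + sub:
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] - gap:
            i -= 1
        else:
            j -= 1
    return i, j


def k_best(query: str, subject: str, k: int = 10, match: int = 5,
           mismatch: int = -4, gap: int = 8) -> list[tuple[int, int, int, int, int]]:
    """Greedy enumeration of non-overlapping local alignments by score.

    Returns (score, s_start, s_end, q_start, q_end) tuples, best first.
    """
    masked = np.zeros(len(subject), dtype=bool)
    out = []
    for _ in range(k):
        H = sw_matrix(query, subject, match, mismatch, gap, masked)
        score, bi, bj = best_cell(H)
        if score <= 0:
            break
        i0, j0 = traceback_start(H, query, subject, match, mismatch, gap,
                                 bi, bj)
        out.append((score, j0, bj, i0, bi))
        masked[j0:bj] = True
    return out
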