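"""Independent brute-force oracles used to cross-check the implementation.

The Smith–Waterman oracle is a textbook affine-gap local-alignment DP
(score only), written against the same cost convention as the package's
aligner — a gap of length k costs open + k*extend — but sharing no code
with it. Numba compiles the inner loops so the full-matrix oracle is
usable on read-vs-20kb instances.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode(seq: str) -> np.ndarray:
    return np.array([_ENC[c] for c in seq], dtype=np.int8)


@njit
def _sw_score(q, t, match, mismatch, gap_open, gap_extend):
    """Optimal local alignment score; N (code 4) never matches."""
    n, m = len(q), len(t)
    NEG = -10**9
    H_prev = np.zeros(m + 1, dtype=np.int64)
    E_prev = np.full(m + 1, NEG, dtype=np.int64)  # gap in target (vertical)
    best = 0
    for i in range(1, n + 1):
        H_cur = np.zeros(m + 1, dtype=np.int64)
        E_cur = np.full(m + 1, NEG, dtype=np.int64)
        F = NEG  # gap in query (horizontal), reset per row
        for j in range(1, m + 1):
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] != 4) else mismatch
            E_cur[j] = max(H_prev[j] - gap_open - gap_extend, E_prev[j] - gap_extend)
            F = max(H_cur[j - 1] - gap_open - gap_extend, F - gap_extend)
            h = max(0, H_prev[j - 1] + s, E_cur[j], F)
            H_cur[j] = h
            if h > best:
                best = h
        H_prev, E_prev = H_cur, E_cur
    return best


def sw_score(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> int:
    """Full-matrix Smith–Waterman score (gap_open/gap_extend as positive costs)."""
    return int(
        _sw_score(encode(query), encode(target), match, mismatch, gap_open, gap_extend)
    )
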