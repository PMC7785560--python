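"""Independent brute-force affine-gap local-alignment oracle.

A full three-matrix quadratic DP written from scratch for the tests:
no pointer matrices — the traceback re-derives each predecessor from
the stored scores.  It follows the same documented conventions as the
package aligner (diag > gap-in-target > gap-in-query on ties; optimal
cell = smallest (i, j) among maxima; gap opening pays open+extend) so
score, path and identity are fully determined, but shares no code with
it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 2
MISMATCH = -2
GAP_OPEN = 4
GAP_EXTEND = 1

NEG = -(1 << 30)


@njit(cache=True)
def _oracle_fill(q, t):  # pragma: no cover - exercised via wrapper
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i - 1, j] - GAP_OPEN - GAP_EXTEND,
                          E[i - 1, j] - GAP_EXTEND)
            F[i, j] = max(H[i, j - 1] - GAP_OPEN - GAP_EXTEND,
                          F[i, j - 1] - GAP_EXTEND)
            s = MATCH if q[i - 1] == t[j - 1] else MISMATCH
            H[i, j] = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
    return H, E, F


def oracle_align(query: str, target: str):
    """(score, identity, query_interval, target_interval, matches, columns).

    Returns None when no positive-scoring local alignment exists.
    """
    if not query or not target:
        return None
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    H, E, F = _oracle_fill(q, t)
    best = int(H.max())
    if best <= 0:
        return None
    bi, bj = np.argwhere(H == best)[0]
    i, j = int(bi), int(bj)
    end_i, end_j = i, j
    matches = columns = 0
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            s = MATCH if q[i - 1] == t[j - 1] else MISMATCH
            if H[i, j] == H[i - 1, j - 1] + s:
                columns += 1
                if q[i - 1] == t[j - 1]:
                    matches += 1
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i, j] == H[i - 1, j] - GAP_OPEN - GAP_EXTEND:
                state = "H"
            i -= 1
        else:
            columns += 1
            if F[i, j] == H[i, j - 1] - GAP_OPEN - GAP_EXTEND:
                state = "H"
            j -= 1
    return best, matches / columns, (i, end_i), (j, end_j), matches, columns


_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_best_segment(read_seq: str, segments):
    """Best (allele_id, strand, result) over segments and strands.

    Ties resolve by score, then identity, then allele id, then '+'.
    """
    best = None
    for seg in segments:
        for strand, q in (("+", read_seq), ("-", _rc(read_seq))):
            res = oracle_align(q, seg.nt_sequence)
            if res is None:
                continue
            key = (res[0], res[1])
            cand = (seg.allele_id, strand, res)
            if (
                best is None
                or key > (best[2][0], best[2][1])
                or (key == (best[2][0], best[2][1])
                    and (seg.allele_id, strand) < (best[0], best[1]))
            ):
                best = cand
    return best


def oracle_filter_decision(
    read_seq: str, segments, min_identity: float = 0.80, min_aligned_nt: int = 30
) -> bool:
    """The 80%-filter decision recomputed from scratch."""
    best = oracle_best_segment(read_seq, segments)
    if best is None:
        return False
    _score, identity, (q0, q1), _tiv, _m, _c = best[2]
    return (q1 - q0) >= min_aligned_nt and identity >= min_identity
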