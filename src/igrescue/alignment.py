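"""Affine-gap local alignment of reads against germline gene segments.

The pipeline's read sorting, the 80% VDJ-identity filter and anchor
projection all rest on one local aligner with fully deterministic
tie-breaking, so the DP is implemented here (numba kernel + Python
traceback) instead of delegating to a library aligner whose tie-break
conventions are opaque.

Conventions (fixed; tests rely on them):

* Scoring: ``match=+2, mismatch=-2``; a gap of length *k* costs
  ``gap_open + k * gap_extend`` with ``gap_open=4, gap_extend=1``
  (first gap base costs 5).
* The optimal cell is the highest-scoring ``H`` cell; ties resolve to
  the smallest query index, then the smallest target index.
* Within a cell, state preference is diagonal > gap-in-target (E,
  consuming query) > gap-in-query (F, consuming target).
* ``identity`` is matches / alignment columns of the traceback under
  these conventions.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MATCH = 2
MISMATCH = -2
GAP_OPEN = 4  # cost of the first gap base (includes its extension)
GAP_EXTEND = 1

_COMP = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

# traceback codes for the H matrix
_H_STOP, _H_DIAG, _H_FROM_E, _H_FROM_F = 0, 1, 2, 3


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@njit(cache=True)
def _fill(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = q.shape[0], t.shape[0]
    neg = -(1 << 30)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), neg, dtype=np.int32)  # gap in target (consumes q)
    F = np.full((n + 1, m + 1), neg, dtype=np.int32)  # gap in query (consumes t)
    ph = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pe = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 = open from H, 1 = extend
    pf = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i - 1, j] - gap_open - gap_extend
            e_ext = E[i - 1, j] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                pe[i, j] = 0
            else:
                E[i, j] = e_ext
                pe[i, j] = 1
            f_open = H[i, j - 1] - gap_open - gap_extend
            f_ext = F[i, j - 1] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                pf[i, j] = 0
            else:
                F[i, j] = f_ext
                pf[i, j] = 1
            s = match if q[i - 1] == t[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            h, p = 0, _H_STOP
            if diag > h:
                h, p = diag, _H_DIAG
            if E[i, j] > h:
                h, p = E[i, j], _H_FROM_E
            if F[i, j] > h:
                h, p = F[i, j], _H_FROM_F
            H[i, j] = h
            ph[i, j] = p
            if h > best:
                best, bi, bj = h, i, j
    return H, ph, pe, pf, best, bi, bj


@dataclass(frozen=True)
class LocalAlignment:
    """A single best local alignment of a query against a target."""

    score: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    matches: int
    columns: int
    #: aligned index pairs (qi, tj); gap columns use -1 on the gapped side
    pairs: tuple

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    def project_to_query(self, target_pos: int) -> int | None:
        """Map a target coordinate onto the query.

        Inside the aligned interval the alignment path is used; outside
        it, the position is extrapolated ungapped from the nearest
        alignment end.  Returns ``None`` if the projected position falls
        outside the query entirely (checked by the caller against query
        length; negative projections return the raw negative value is
        never useful, so ``None``).
        """
        if target_pos < self.target_start:
            proj = self.query_start - (self.target_start - target_pos)
            return proj if proj >= 0 else None
        if target_pos >= self.target_end:
            return self.query_end + (target_pos - self.target_end)
        last_q = self.query_start
        for qi, tj in self.pairs:
            if qi >= 0:
                last_q = qi
            if tj == target_pos:
                return qi if qi >= 0 else last_q
        return None


def smith_waterman(query: str, target: str) -> LocalAlignment | None:
    """Best local alignment under the module's fixed conventions.

    Returns ``None`` when the best score is 0 (no positive-scoring
    local similarity).
    """
    if not query or not target:
        return None
    q, t = encode(query), encode(target)
    H, ph, pe, pf, best, bi, bj = _fill(
        q, t, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND
    )
    if best <= 0:
        return None
    # deterministic best cell: smallest i then smallest j among maxima
    where = np.argwhere(H == best)
    bi, bj = int(where[0][0]), int(where[0][1])
    pairs: list[tuple[int, int]] = []
    matches = 0
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            p = ph[i, j]
            if p == _H_STOP:
                break
            if p == _H_DIAG:
                pairs.append((i - 1, j - 1))
                if q[i - 1] == t[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == _H_FROM_E:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            pairs.append((i - 1, -1))
            nxt = pe[i, j]
            i -= 1
            state = "H" if nxt == 0 else "E"
        else:
            pairs.append((-1, j - 1))
            nxt = pf[i, j]
            j -= 1
            state = "H" if nxt == 0 else "F"
    pairs.reverse()
    return LocalAlignment(
        score=int(best),
        query_start=i,
        query_end=bi,
        target_start=j,
        target_end=bj,
        matches=matches,
        columns=len(pairs),
        pairs=tuple(pairs),
    )


def hamming_identity(a: str, b: str) -> float:
    """Fraction of equal positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming_identity requires equal lengths")
    if not a:
        return 1.0
    return sum(x == y for x, y in zip(a, b)) / len(a)
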