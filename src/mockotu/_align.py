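"""Pairwise alignment kernels.

Two dynamic-programming kernels, both affine-gap with the package-wide
scoring scheme (match +1, mismatch -2, first gap column -10, each further
gap column -1):

* a global aligner with free (unscored) terminal gaps, returning per-column
  operation traces, used for OTU divergence calculations;
* a local (Smith-Waterman) aligner returning match/aligned column counts,
  used for best-hit taxonomy.

Both are numba-jitted; sequences are passed as uint8 code arrays
(A=0, C=1, G=2, T=3; anything else = 4, which matches no base).

Tie-breaking is fixed so results are deterministic: when scores tie, the
diagonal (match/mismatch) state is preferred over a gap consuming the first
sequence ("up"), which is preferred over a gap consuming the second
("left"); the alignment end point with the smallest terminal overhang wins.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -2
GAP_OPEN = -10  # cost of the first column of a gap run
GAP_EXTEND = -1  # cost of each subsequent column

_NEG = -(10**8)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (non-ACGT -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# Column op codes emitted by the global kernel
OP_MATCH = 0
OP_MISMATCH = 1
OP_GAP_IN_B = 2  # column consumes a only (gap in b)
OP_GAP_IN_A = 3  # column consumes b only (gap in a)
OP_TERM_A = 4  # terminal overhang column from a
OP_TERM_B = 5  # terminal overhang column from b


@njit(cache=True)
def _global_kernel(a, b):  # pragma: no cover - exercised via global_align
    n = a.shape[0]
    m = b.shape[0]
    SM = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    SX = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    SY = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    PM = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=M 1=X 2=Y 3=boundary
    PX = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=M 1=X
    PY = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=M 2=Y

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            # M state: predecessor is best of M/X/Y at (i-1,j-1), or the
            # free boundary when the diagonal cell sits on an edge.
            bp = SM[i - 1, j - 1]
            ptr = 0
            if SX[i - 1, j - 1] > bp:
                bp = SX[i - 1, j - 1]
                ptr = 1
            if SY[i - 1, j - 1] > bp:
                bp = SY[i - 1, j - 1]
                ptr = 2
            if (i - 1 == 0 or j - 1 == 0) and 0 > bp:
                bp = 0
                ptr = 3
            SM[i, j] = bp + s
            PM[i, j] = ptr
            # X state: gap in b, consumes a[i-1]
            mo = SM[i - 1, j] + GAP_OPEN
            xe = SX[i - 1, j] + GAP_EXTEND
            if mo >= xe:
                SX[i, j] = mo
                PX[i, j] = 0
            else:
                SX[i, j] = xe
                PX[i, j] = 1
            # Y state: gap in a, consumes b[j-1]
            mo = SM[i, j - 1] + GAP_OPEN
            ye = SY[i, j - 1] + GAP_EXTEND
            if mo >= ye:
                SY[i, j] = mo
                PY[i, j] = 0
            else:
                SY[i, j] = ye
                PY[i, j] = 2

    # End point: best cell on the last row or column (trailing overhang is
    # free); scanned from (n, m) outward so smaller overhangs win ties.
    best = _NEG - 1
    bi = n
    bj = m
    bstate = 0
    for j in range(m, 0, -1):
        v = SM[n, j]
        st = 0
        if SX[n, j] > v:
            v = SX[n, j]
            st = 1
        if SY[n, j] > v:
            v = SY[n, j]
            st = 2
        if v > best:
            best = v
            bi = n
            bj = j
            bstate = st
    for i in range(n, 0, -1):
        v = SM[i, m]
        st = 0
        if SX[i, m] > v:
            v = SX[i, m]
            st = 1
        if SY[i, m] > v:
            v = SY[i, m]
            st = 2
        if v > best:
            best = v
            bi = i
            bj = m
            bstate = st

    # Traceback, emitting column ops right-to-left.
    ops = np.empty(n + m, dtype=np.int8)
    apos = np.empty(n + m, dtype=np.int32)  # a-coordinate of each column
    k = 0
    for t in range(m - bj):  # trailing b overhang
        ops[k] = OP_TERM_B
        apos[k] = bi
        k += 1
    for t in range(n - bi):  # trailing a overhang
        ops[k] = OP_TERM_A
        apos[k] = n - 1 - t
        k += 1
    i = bi
    j = bj
    st = bstate
    while True:
        if st == 0:
            ops[k] = OP_MATCH if a[i - 1] == b[j - 1] else OP_MISMATCH
            apos[k] = i - 1
            k += 1
            p = PM[i, j]
            i -= 1
            j -= 1
            if p == 3:
                break
            st = p
        elif st == 1:
            ops[k] = OP_GAP_IN_B
            apos[k] = i - 1
            k += 1
            st = PX[i, j]
            i -= 1
        else:
            ops[k] = OP_GAP_IN_A
            apos[k] = i
            k += 1
            st = PY[i, j]
            j -= 1
    for t in range(i):  # leading a overhang
        ops[k] = OP_TERM_A
        apos[k] = i - 1 - t
        k += 1
    for t in range(j):  # leading b overhang
        ops[k] = OP_TERM_B
        apos[k] = 0
        k += 1
    return best, ops[:k][::-1].copy(), apos[:k][::-1].copy()


@njit(cache=True)
def _local_kernel(a, b):  # pragma: no cover - exercised via local_align
    n = a.shape[0]
    m = b.shape[0]
    SM = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    SX = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    SY = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    PM = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=M 1=X 2=Y 3=start
    PX = np.zeros((n + 1, m + 1), dtype=np.int8)
    PY = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else MISMATCH
            bp = SM[i - 1, j - 1]
            ptr = 0
            if SX[i - 1, j - 1] > bp:
                bp = SX[i - 1, j - 1]
                ptr = 1
            if SY[i - 1, j - 1] > bp:
                bp = SY[i - 1, j - 1]
                ptr = 2
            if 0 > bp:
                bp = 0
                ptr = 3
            SM[i, j] = bp + s
            PM[i, j] = ptr
            mo = SM[i - 1, j] + GAP_OPEN
            xe = SX[i - 1, j] + GAP_EXTEND
            if mo >= xe:
                SX[i, j] = mo
                PX[i, j] = 0
            else:
                SX[i, j] = xe
                PX[i, j] = 1
            mo = SM[i, j - 1] + GAP_OPEN
            ye = SY[i, j - 1] + GAP_EXTEND
            if mo >= ye:
                SY[i, j] = mo
                PY[i, j] = 0
            else:
                SY[i, j] = ye
                PY[i, j] = 2
            if SM[i, j] > best:
                best = SM[i, j]
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0
    match_cols = 0
    aligned_cols = 0
    i = bi
    j = bj
    st = 0
    while True:
        if st == 0:
            aligned_cols += 1
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                match_cols += 1
            p = PM[i, j]
            i -= 1
            j -= 1
            if p == 3:
                break
            st = p
        elif st == 1:
            aligned_cols += 1
            st = PX[i, j]
            i -= 1
        else:
            aligned_cols += 1
            st = PY[i, j]
            j -= 1
    return best, match_cols, aligned_cols


def global_align_ops(a: str, b: str):
    """Global alignment with free end gaps; returns (score, ops, apos).

    ``ops`` is the per-column operation code array (left to right) and
    ``apos`` the a-sequence coordinate associated with each column.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return _global_kernel(encode(a), encode(b))


def local_align_counts(a: str, b: str):
    """Local alignment; returns (score, match_columns, aligned_columns)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return _local_kernel(encode(a), encode(b))
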