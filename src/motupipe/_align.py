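"""Affine-gap alignment kernels backing percent-identity computation.

Scoring follows the usual nucleotide conventions: a positive match score,
a mismatch penalty, and affine gaps where a gap of length L costs
``gap_open + gap_extend * L``.  ``N`` never counts as a match.

Percent identity must be a deterministic function of the two sequences,
so among all score-optimal global (or local) alignments the kernels
report the one maximizing the number of identical aligned bases, ties
broken toward fewer alignment columns.  This is achieved by packing
(score, matches, columns) into a single int64 key that orders
lexicographically and is additive along an alignment path:

    key = (score + 2^20) << 24 | matches << 12 | (4095 - columns)

Field widths cap sequence length at 2000 bp (columns <= 4095), ample for
~450 bp amplicons.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_LEN = 2000

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """Map an A/C/G/T/N string to codes 0..4 (4 = N)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _gotoh_global(a, b, match, mismatch, go, ge):  # pragma: no cover - jitted
    la = a.shape[0]
    lb = b.shape[0]
    BASE = ((1 << 20) << 24) + 4095
    NEG = -(1 << 60)
    SM = (match << 24) + (1 << 12) - 1
    SX = ((-mismatch) << 24) - 1
    GO = ((-(go + ge)) << 24) - 1
    GE = ((-ge) << 24) - 1

    Mp = np.empty(lb + 1, np.int64)
    Xp = np.empty(lb + 1, np.int64)
    Yp = np.empty(lb + 1, np.int64)
    Mc = np.empty(lb + 1, np.int64)
    Xc = np.empty(lb + 1, np.int64)
    Yc = np.empty(lb + 1, np.int64)

    Mp[0] = BASE
    Xp[0] = NEG
    Yp[0] = NEG
    for j in range(1, lb + 1):
        Mp[j] = NEG
        Xp[j] = NEG
        Yp[j] = (BASE + GO) if j == 1 else (Yp[j - 1] + GE)

    for i in range(1, la + 1):
        Mc[0] = NEG
        Yc[0] = NEG
        Xc[0] = (BASE + GO) if i == 1 else (Xp[0] + GE)
        ai = a[i - 1]
        for j in range(1, lb + 1):
            diag = Mp[j - 1]
            if Xp[j - 1] > diag:
                diag = Xp[j - 1]
            if Yp[j - 1] > diag:
                diag = Yp[j - 1]
            if ai == b[j - 1] and ai != 4:
                Mc[j] = diag + SM
            else:
                Mc[j] = diag + SX
            opn = Mp[j] if Mp[j] > Yp[j] else Yp[j]
            ext = Xp[j] + GE
            opn = opn + GO
            Xc[j] = ext if ext > opn else opn
            opn2 = Mc[j - 1] if Mc[j - 1] > Xc[j - 1] else Xc[j - 1]
            ext2 = Yc[j - 1] + GE
            opn2 = opn2 + GO
            Yc[j] = ext2 if ext2 > opn2 else opn2
        for j in range(lb + 1):
            Mp[j] = Mc[j]
            Xp[j] = Xc[j]
            Yp[j] = Yc[j]

    best = Mp[lb]
    if Xp[lb] > best:
        best = Xp[lb]
    if Yp[lb] > best:
        best = Yp[lb]
    score = (best >> 24) - (1 << 20)
    matches = (best >> 12) & 4095
    cols = 4095 - (best & 4095)
    return score, matches, cols


@njit(cache=True)
def _gotoh_local(a, b, match, mismatch, go, ge):  # pragma: no cover - jitted
    la = a.shape[0]
    lb = b.shape[0]
    BASE = ((1 << 20) << 24) + 4095
    NEG = -(1 << 60)
    SM = (match << 24) + (1 << 12) - 1
    SX = ((-mismatch) << 24) - 1
    GO = ((-(go + ge)) << 24) - 1
    GE = ((-ge) << 24) - 1

    Mp = np.full(lb + 1, NEG, np.int64)
    Xp = np.full(lb + 1, NEG, np.int64)
    Yp = np.full(lb + 1, NEG, np.int64)
    Mc = np.empty(lb + 1, np.int64)
    Xc = np.empty(lb + 1, np.int64)
    Yc = np.empty(lb + 1, np.int64)

    best = BASE  # the empty local alignment
    for i in range(1, la + 1):
        Mc[0] = NEG
        Xc[0] = NEG
        Yc[0] = NEG
        ai = a[i - 1]
        for j in range(1, lb + 1):
            diag = BASE  # local alignments may start anywhere
            if Mp[j - 1] > diag:
                diag = Mp[j - 1]
            if Xp[j - 1] > diag:
                diag = Xp[j - 1]
            if Yp[j - 1] > diag:
                diag = Yp[j - 1]
            if ai == b[j - 1] and ai != 4:
                Mc[j] = diag + SM
            else:
                Mc[j] = diag + SX
            opn = Mp[j] if Mp[j] > Yp[j] else Yp[j]
            ext = Xp[j] + GE
            opn = opn + GO
            Xc[j] = ext if ext > opn else opn
            opn2 = Mc[j - 1] if Mc[j - 1] > Xc[j - 1] else Xc[j - 1]
            ext2 = Yc[j - 1] + GE
            opn2 = opn2 + GO
            Yc[j] = ext2 if ext2 > opn2 else opn2
            if Mc[j] > best:
                best = Mc[j]
        for j in range(lb + 1):
            Mp[j] = Mc[j]
            Xp[j] = Xc[j]
            Yp[j] = Yc[j]

    score = (best >> 24) - (1 << 20)
    matches = (best >> 12) & 4095
    cols = 4095 - (best & 4095)
    return score, matches, cols


def _check(a: str, b: str) -> None:
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if len(a) > MAX_LEN or len(b) > MAX_LEN:
        raise ValueError(
            f"sequences longer than {MAX_LEN} bp are not supported by the identity engine"
        )


def global_stats(a: str, b: str, match: int = 2, mismatch: int = 3,
                 gap_open: int = 5, gap_extend: int = 2) -> tuple[int, int, int]:
    """Optimal global alignment of *a* and *b*.

    Returns ``(score, matches, columns)`` for the score-optimal global
    alignment with the most identical aligned bases.
    """
    _check(a, b)
    s, m, c = _gotoh_global(encode(a), encode(b), match, mismatch, gap_open, gap_extend)
    return int(s), int(m), int(c)


def local_stats(a: str, b: str, match: int = 2, mismatch: int = 3,
                gap_open: int = 5, gap_extend: int = 2) -> tuple[int, int, int]:
    """Best local (Smith-Waterman) alignment; same tie conventions as
    :func:`global_stats`."""
    _check(a, b)
    s, m, c = _gotoh_local(encode(a), encode(b), match, mismatch, gap_open, gap_extend)
    return int(s), int(m), int(c)
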