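"""Low-level pairwise alignment kernels.

The whole pipeline hangs on a single similarity definition: two sequences
are "similar" when their best local alignment covers at least a given
fraction of the shorter sequence at a given percent identity.  The kernel
here is a plain Smith-Waterman with linear gap costs, JIT-compiled with
numba; read-versus-long-reference screening narrows it to a window around
seeded diagonals (see :mod:`repeatome.annotate`).

Scoring is match +2 / mismatch -3 / gap -5.  At the 90 % identity regime
the expected score per aligned column is positive (0.9*2 - 0.1*3 = 1.5),
so optimal local alignments extend through the mismatch density the
similarity rule is meant to tolerate instead of fragmenting.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 2
MISMATCH = -3
GAP = -5

_COMP = np.zeros(256, dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0, C=1, G=2, T=3).

    Raises ``ValueError`` on empty input or characters outside {A,C,G,T}.
    """
    if not seq:
        raise ValueError("empty sequence")
    arr = _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq.upper()) - set("ACGT"))
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    return arr


def revcomp_codes(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded sequence (0<->3, 1<->2)."""
    return (3 - arr)[::-1].copy()


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@njit(cache=True)
def _sw(a, b, match, mismatch, gap):  # pragma: no cover - exercised via wrapper
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    P = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            v = H[i - 1, j - 1] + s
            p = 1
            u = H[i - 1, j] + gap
            if u > v:
                v = u
                p = 2
            lf = H[i, j - 1] + gap
            if lf > v:
                v = lf
                p = 3
            if v <= 0:
                v = 0
                p = 0
            H[i, j] = v
            P[i, j] = p
            if v > best:
                best = v
                bi = i
                bj = j
    i = bi
    j = bj
    matches = 0
    cols = 0
    while i > 0 and j > 0 and P[i, j] != 0:
        p = P[i, j]
        if p == 1:
            cols += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return best, matches, cols, i, bi, j, bj


def sw_align(a: np.ndarray, b: np.ndarray):
    """Best local alignment of two encoded sequences.

    Returns ``(score, matches, columns, a_begin, a_end, b_begin, b_end)``
    with half-open coordinates on each sequence.  Ties in the dynamic
    program are broken deterministically (diagonal > up > left; first
    maximum encountered in row-major order), so results are reproducible.
    """
    return _sw(a, b, MATCH, MISMATCH, GAP)


def alignment_identity_span(a: np.ndarray, b: np.ndarray):
    """Identity and shorter-sequence span of the optimal local alignment.

    Returns ``(identity, span)`` where identity = matches / alignment
    columns (gap columns included) and span = number of residues of the
    *shorter* input consumed by the alignment.  ``(0.0, 0)`` when the
    optimal alignment is empty.
    """
    score, matches, cols, ab, ae, bb, be = sw_align(a, b)
    if cols == 0:
        return 0.0, 0
    span_a = ae - ab
    span_b = be - bb
    span = span_a if a.shape[0] <= b.shape[0] else span_b
    return matches / cols, span


@njit(cache=True)
def match_autocorrelation(arr, lag):  # pragma: no cover - tiny helper
    n = arr.shape[0] - lag
    if n <= 0:
        return 0.0
    hits = 0
    for i in range(n):
        if arr[i] == arr[i + lag]:
            hits += 1
    return hits / n
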