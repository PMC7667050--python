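"""Candidate generation and edge decision kernels for the read graph.

All-versus-all alignment of N reads is quadratic; the production graph
builder instead joins reads on shared 9-mers.  The choice k = 9 is not a
heuristic: any local alignment spanning s > 80 columns at >= 90 % identity
has at most e <= s/10 errors, whose e+1 gapless segments contain s - e
matches, so the longest segment is at least ceil((s-e)/(e+1)) >= 9
whenever s > 9e + 8, which holds for every alignment the similarity rule
accepts (s >= 83).  A qualifying pair therefore always shares an exact
9-mer on the alignment's strand, and the join misses nothing.

Shared 9-mers between *unrelated* 150 bp reads are common (~15 % of
pairs), so candidates pass a second, cheap gate before the full
Smith-Waterman: the best-scoring gapless run (Kadane maximum subarray of
+2 match / -3 mismatch) on each seeded diagonal.  A qualifying alignment
whose errors are substitutions scores >= ~120 on its diagonal; unrelated
seeds rarely exceed ~25.  The gate threshold (default 30) keeps the gate
conservative for alignments with up to two short indels; data dominated
by indel errors would need the gate disabled (``gapless_screen_min=0``).

Everything is deterministic and symmetric: each pair is evaluated in a
canonical frame (lexicographically smaller sequence first), so relabeling
or reordering reads cannot change any edge.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._align import GAP, MATCH, MISMATCH, _sw

KMER = 9


@njit(cache=True)
def _enumerate_kmers(codes, lens, k):
    n = codes.shape[0]
    total = 0
    for i in range(n):
        if lens[i] >= k:
            total += lens[i] - k + 1
    km = np.empty(total, np.int64)
    ri = np.empty(total, np.int32)
    pos = np.empty(total, np.int16)
    ori = np.empty(total, np.uint8)
    mask = (1 << (2 * k)) - 1
    idx = 0
    for i in range(n):
        L = lens[i]
        if L < k:
            continue
        f = 0
        r = 0
        for t in range(k):
            f = (f << 2) | codes[i, t]
            r |= (3 - codes[i, t]) << (2 * t)
        p = 0
        while True:
            c = f if f <= r else r
            km[idx] = c
            ri[idx] = i
            pos[idx] = p
            ori[idx] = 0 if f <= r else 1
            idx += 1
            if p + k >= L:
                break
            nxt = codes[i, p + k]
            f = ((f << 2) | nxt) & mask
            r = (r >> 2) | ((3 - nxt) << (2 * (k - 1)))
            p += 1
    return km, ri, pos, ori


@njit(cache=True)
def _count_candidates(km, ri):
    total = 0
    n = km.shape[0]
    a = 0
    while a < n:
        b = a + 1
        while b < n and km[b] == km[a]:
            b += 1
        run = b - a
        if run > 1:
            total += run * (run - 1) // 2
        a = b
    return total


@njit(cache=True)
def _emit_candidates(km, ri, pos, ori, lens, k, out):
    idx = 0
    n = km.shape[0]
    a = 0
    while a < n:
        b = a + 1
        while b < n and km[b] == km[a]:
            b += 1
        for u in range(a, b):
            for v in range(u + 1, b):
                iu = ri[u]
                iv = ri[v]
                if iu == iv:
                    continue
                if iu < iv:
                    i, j = iu, iv
                    pi, pj = pos[u], pos[v]
                    s = ori[u] ^ ori[v]
                else:
                    i, j = iv, iu
                    pi, pj = pos[v], pos[u]
                    s = ori[u] ^ ori[v]
                if s == 1:
                    pjj = lens[j] - k - pj
                else:
                    pjj = pj
                d = pi - pjj
                key = ((np.int64(i) * 2097152 + j) * 2 + s) * 2048 + (d + 1024)
                out[idx] = key
                idx += 1
        a = b
    return idx


@njit(cache=True)
def _kadane_diag(x, lx, y, ly, d, match, mismatch):
    t0 = d if d > 0 else 0
    t1 = lx if lx < ly + d else ly + d
    best = 0
    cur = 0
    for t in range(t0, t1):
        cur += match if x[t] == y[t - d] else mismatch
        if cur < 0:
            cur = 0
        elif cur > best:
            best = cur
    return best


@njit(cache=True)
def _decide_edges(
    keys,
    codes,
    rc_codes,
    lens,
    lex_rank,
    min_identity,
    min_len_frac,
    screen_min,
    both_strands,
):
    m = keys.shape[0]
    out_i = np.empty(m, np.int32)
    out_j = np.empty(m, np.int32)
    n_edges = 0
    a = 0
    while a < m:
        key = keys[a]
        pair = key // (2 * 2048)
        i = np.int32(pair // 2097152)
        j = np.int32(pair % 2097152)
        b = a
        while b < m and keys[b] // (2 * 2048) == pair:
            b += 1
        # canonical frame: lexicographically smaller sequence is x
        if lex_rank[j] < lex_rank[i]:
            x, y = j, i
            swapped = True
        else:
            x, y = i, j
            swapped = False
        lx = lens[x]
        ly = lens[y]
        shorter = lx if lx < ly else ly
        min_span = int(np.ceil(min_len_frac * shorter - 1e-9))
        edge = False
        for strand in range(2):
            if edge:
                break
            if strand == 1 and not both_strands:
                break
            gate = False
            for t in range(a, b):
                k2 = keys[t]
                s = (k2 // 2048) % 2
                if s != strand:
                    continue
                d = np.int32(k2 % 2048) - 1024
                if swapped:
                    if strand == 0:
                        dc = -d
                    else:
                        dc = d + lens[j] - lens[i]  # original frame was i vs j
                else:
                    dc = d
                yseq = codes[y] if strand == 0 else rc_codes[y]
                if screen_min <= 0 or (
                    _kadane_diag(codes[x], lx, yseq, ly, dc, MATCH, MISMATCH)
                    >= screen_min
                ):
                    gate = True
                    break
            if not gate:
                continue
            yseq = codes[y][:ly] if strand == 0 else rc_codes[y][:ly]
            score, matches, cols, ab, ae, bb, be = _sw(
                codes[x][:lx], yseq, MATCH, MISMATCH, GAP
            )
            if cols == 0:
                continue
            span = (ae - ab) if lx <= ly else (be - bb)
            if span >= min_span and matches >= min_identity * cols - 1e-9:
                edge = True
        if edge:
            out_i[n_edges] = i
            out_j[n_edges] = j
            n_edges += 1
        a = b
    return out_i[:n_edges], out_j[:n_edges]


def candidate_edges(
    codes: np.ndarray,
    lens: np.ndarray,
    rc_codes: np.ndarray,
    lex_rank: np.ndarray,
    min_identity: float,
    min_len_frac: float,
    screen_min: int,
    both_strands: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Edges of the similarity graph as two parallel index arrays."""
    if codes.shape[0] > 2_000_000:
        raise ValueError("too many reads for the candidate index (max 2,000,000)")
    km, ri, pos, ori = _enumerate_kmers(codes, lens, KMER)
    order = np.argsort(km, kind="stable")
    km = km[order]
    ri = ri[order]
    pos = pos[order]
    ori = ori[order]
    n_cand = _count_candidates(km, ri)
    buf = np.empty(n_cand, np.int64)
    used = _emit_candidates(km, ri, pos, ori, lens, KMER, buf)
    keys = np.unique(buf[:used])
    return _decide_edges(
        keys,
        codes,
        rc_codes,
        lens,
        lex_rank,
        min_identity,
        min_len_frac,
        screen_min,
        both_strands,
    )
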