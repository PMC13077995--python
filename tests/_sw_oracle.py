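"""Exhaustive affine-gap local-alignment oracle.

Independent of the package's segment finder: a full Gotoh Smith-Waterman
matrix over the whole genome (both strands) with start-cell tracking,
applied recursively to the unaligned query flanks to enumerate all
segments of a (possibly chimeric) read.  Numba-compiled so the full DP is
affordable on reads up to a few hundred nt.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _enc(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8).copy()


@njit(cache=False)
def _sw_fill(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = len(q), len(r)
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    E = np.full((n + 1, m + 1), -1e18)
    F = np.full((n + 1, m + 1), -1e18)
    sHq = np.zeros((n + 1, m + 1), dtype=np.int32)
    sHr = np.zeros((n + 1, m + 1), dtype=np.int32)
    sEq = np.zeros((n + 1, m + 1), dtype=np.int32)
    sEr = np.zeros((n + 1, m + 1), dtype=np.int32)
    sFq = np.zeros((n + 1, m + 1), dtype=np.int32)
    sFr = np.zeros((n + 1, m + 1), dtype=np.int32)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # E: gap consuming reference
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                sEq[i, j], sEr[i, j] = sHq[i, j - 1], sHr[i, j - 1]
            else:
                E[i, j] = e_ext
                sEq[i, j], sEr[i, j] = sEq[i, j - 1], sEr[i, j - 1]
            # F: gap consuming query
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                sFq[i, j], sFr[i, j] = sHq[i - 1, j], sHr[i - 1, j]
            else:
                F[i, j] = f_ext
                sFq[i, j], sFr[i, j] = sFq[i - 1, j], sFr[i - 1, j]
            sub = match if q[i - 1] == r[j - 1] else mismatch
            diag = H[i - 1, j - 1] + sub
            h = diag
            sq = sHq[i - 1, j - 1] if H[i - 1, j - 1] > 0 else i - 1
            sr = sHr[i - 1, j - 1] if H[i - 1, j - 1] > 0 else j - 1
            if E[i, j] > h:
                h = E[i, j]
                sq, sr = sEq[i, j], sEr[i, j]
            if F[i, j] > h:
                h = F[i, j]
                sq, sr = sFq[i, j], sFr[i, j]
            if h < 0:
                h = 0.0
                sq, sr = i, j
            H[i, j] = h
            sHq[i, j], sHr[i, j] = sq, sr
            if h > best:
                best = h
                bi, bj = i, j
    return best, bi, bj, sHq[bi, bj], sHr[bi, bj]


def best_local_alignment(query: str, ref: str,
                         scoring=(1, -2, -4, -2)):
    """Best local alignment (score, q_start, q_end, r_start, r_end)."""
    match, mismatch, gap_open, gap_extend = scoring
    score, bi, bj, sq, sr = _sw_fill(_enc(query), _enc(ref),
                                     float(match), float(mismatch),
                                     float(gap_open), float(gap_extend))
    return float(score), int(sq), int(bi), int(sr), int(bj)


def oracle_segments(read: str, genome_seq: str, min_score: float = 60,
                    min_len: int = 60, scoring=(1, -2, -4, -2)):
    """All local-alignment segments of a read against genome/revcomp.

    Recursively aligns the read, records the best segment over both
    strands, and recurses on the unaligned query flanks.  Returns a list
    of dicts with query/ref intervals (read frame, 0-based half-open),
    strand and score.
    """
    out = []

    def rec(qseq: str, offset: int) -> None:
        if len(qseq) < min_len:
            return
        best = None
        for strand in "+-":
            q = qseq if strand == "+" else _rc(qseq)
            score, qs, qe, rs, re_ = best_local_alignment(q, genome_seq, scoring)
            if strand == "-":
                qs, qe = len(qseq) - qe, len(qseq) - qs
            if best is None or score > best[0]:
                best = (score, qs, qe, rs, re_, strand)
        score, qs, qe, rs, re_, strand = best
        if score < min_score:
            return
        out.append({"query_start": offset + qs, "query_end": offset + qe,
                    "ref_start": rs, "ref_end": re_, "strand": strand,
                    "score": score})
        rec(qseq[:qs], offset)
        rec(qseq[qe:], offset + qe)

    rec(read, 0)
    out.sort(key=lambda s: s["query_start"])
    return out


def segments_agree(production, oracle, tol: int = 3) -> bool:
    """1:1 match of segment sets: same strand, ref ends within ``tol`` nt."""
    if len(production) != len(oracle):
        return False
    used = [False] * len(oracle)
    for seg in production:
        hit = False
        for i, o in enumerate(oracle):
            if used[i]:
                continue
            if (seg.strand == o["strand"]
                    and abs(seg.ref_start - o["ref_start"]) <= tol
                    and abs(seg.ref_end - o["ref_end"]) <= tol):
                used[i] = True
                hit = True
                break
        if not hit:
            return False
    return True
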