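"""K-mer-seeded local alignment with affine gaps.

The scoring scheme follows the WU-BLAST-style constants the pipeline
was built around: match +1, mismatch -3, affine gaps (a gap of length k
costs ``gap_open + (k-1) * gap_extend``).  The dynamic program is a
full Smith-Waterman/Gotoh compiled with numba; candidate pair discovery
uses exact shared k-mers on canonical strands, so the expensive DP runs
only on read pairs that plausibly overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from repeatscape.seqio import revcomp

_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment between two sequences.

    ``length`` counts alignment columns (including gaps); ``identity``
    is percent matching columns; spans are 0-based half-open on the
    forward orientation of each input.
    """

    score: int
    length: int
    identity: float
    matches: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str = "+"


@njit(cache=False)
def _gotoh_local(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    NEG = -10 ** 6
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    # traceback: 0 stop, 1 diag, 2 from E (gap consumes b), 3 from F (gap consumes a)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 => opened from H
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            eo = H[i, j - 1] + gap_open
            ee = E[i, j - 1] + gap_extend
            if eo >= ee:
                E[i, j] = eo
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
            fo = H[i - 1, j] + gap_open
            fe = F[i - 1, j] + gap_extend
            if fo >= fe:
                F[i, j] = fo
                ptrF[i, j] = 1
            else:
                F[i, j] = fe
            if ai == b[j - 1] and ai < 4:
                s = H[i - 1, j - 1] + match
            else:
                s = H[i - 1, j - 1] + mismatch
            h = 0
            p = 0
            if s > h:
                h = s
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback
    i, j = bi, bj
    matches = 0
    length = 0
    state = 0  # 0: in H, 2: in E, 3: in F
    while i > 0 and j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                length += 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            length += 1
            opened = ptrE[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:
            length += 1
            opened = ptrF[i, j]
            i -= 1
            if opened == 1:
                state = 0
    return best, matches, length, i, bi, j, bj


def local_align(a: str, b: str, scoring: Scoring = Scoring()) -> Optional[LocalAlignment]:
    """Best local alignment of ``a`` vs ``b`` on the given strand only."""
    score, matches, length, a0, a1, b0, b1 = _gotoh_local(
        encode(a), encode(b),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    if score <= 0 or length == 0:
        return None
    return LocalAlignment(
        score=int(score), length=int(length),
        identity=100.0 * matches / length, matches=int(matches),
        a_start=int(a0), a_end=int(a1), b_start=int(b0), b_end=int(b1),
    )


def best_local_alignment(
    a: str, b: str, scoring: Scoring = Scoring(), both_strands: bool = True
) -> Optional[LocalAlignment]:
    """Best local alignment over both strands of ``b`` (forward wins ties).

    Spans on the reverse strand are reported in ``b``'s forward
    coordinates.
    """
    fwd = local_align(a, b, scoring)
    if not both_strands:
        return fwd
    rev = local_align(a, revcomp(b), scoring)
    if rev is not None and (fwd is None or rev.score > fwd.score):
        m = len(b)
        return LocalAlignment(
            score=rev.score, length=rev.length, identity=rev.identity,
            matches=rev.matches, a_start=rev.a_start, a_end=rev.a_end,
            b_start=m - rev.b_end, b_end=m - rev.b_start, strand="-",
        )
    return fwd


# ---------------------------------------------------------------------------
# K-mer seeding
# ---------------------------------------------------------------------------

def canonical_kmers(seq: str, k: int) -> set[int]:
    """Integer codes of the canonical (strand-minimum) k-mers of ``seq``.

    K-mers containing non-ACGT symbols are skipped.
    """
    codes = encode(seq)
    rc = 3 - codes[::-1]
    out: set[int] = set()
    n = len(codes)
    if n < k:
        return out
    fwd = _roll(codes, k)
    rev = _roll(rc, k)[::-1]  # rev[i] = revcomp of window starting at i
    valid = _valid_windows(codes, k)
    for i in range(n - k + 1):
        if valid[i]:
            out.add(int(min(fwd[i], rev[i])))
    return out


def _roll(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed 2-bit integer for every k-window (garbage where non-ACGT)."""
    vals = np.zeros(len(codes) - k + 1, dtype=np.int64)
    base = np.minimum(codes, 3).astype(np.int64)
    for off in range(k):
        vals = vals * 4 + base[off:off + len(vals)]
    return vals


def _valid_windows(codes: np.ndarray, k: int) -> np.ndarray:
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    return (cs[k:] - cs[:-k]) == 0


# ---------------------------------------------------------------------------
# All-vs-all machinery: seeded candidates + banded DP on the seed diagonal
# ---------------------------------------------------------------------------

@njit(cache=False)
def _gather_for_read(i, grp, pos, flag, k_starts, read_k, pos_k, flag_k,
                     cnt_f, cnt_r, diag_f, diag_r, touched,
                     min_shared):  # pragma: no cover
    """Partners j > i sharing canonical k-mers with read i.

    Returns (j, orient, diag_code, count) arrays; orient 1 means the
    match is against the reverse complement of j.  ``diag_code`` is the
    DP diagonal pb - pa for forward matches and pa + pb for reverse
    matches (the caller converts the latter to a DP diagonal once the
    partner length is known).  cnt_*/diag_*/touched are reusable
    scratch arrays.
    """
    ntouch = 0
    for e in range(grp.shape[0]):
        g = grp[e]
        p = pos[e]
        f = flag[e]
        for t in range(k_starts[g], k_starts[g + 1]):
            j = read_k[t]
            if j <= i:
                continue
            if cnt_f[j] == 0 and cnt_r[j] == 0:
                touched[ntouch] = j
                ntouch += 1
            if f == flag_k[t]:
                if cnt_f[j] == 0:
                    diag_f[j] = pos_k[t] - p
                cnt_f[j] += 1
            else:
                if cnt_r[j] == 0:
                    diag_r[j] = p + pos_k[t]
                cnt_r[j] += 1
    out_j = np.empty(ntouch, dtype=np.int32)
    out_o = np.empty(ntouch, dtype=np.int8)
    out_d = np.empty(ntouch, dtype=np.int32)
    out_c = np.empty(ntouch, dtype=np.int32)
    m = 0
    for t in range(ntouch):
        j = touched[t]
        cf = cnt_f[j]
        cr = cnt_r[j]
        if cf + cr >= min_shared:
            out_j[m] = j
            if cf >= cr:
                out_o[m] = 0
                out_d[m] = diag_f[j]
            else:
                out_o[m] = 1
                out_d[m] = diag_r[j]
            out_c[m] = cf + cr
            m += 1
        cnt_f[j] = 0
        cnt_r[j] = 0
    return out_j[:m], out_o[:m], out_d[:m], out_c[:m]


@njit(cache=False)
def _banded_gotoh(a, b, diag, band, H, E, F, ptr, ptrE, ptrF,
                  match, mismatch, go, ge):  # pragma: no cover
    """Local Gotoh restricted to |(j - i) - diag| <= band.

    Buffers are (maxlen+1, 2*band+1) and reused across calls; offset
    o maps to column j = i + diag + o - band.  Returns the same tuple
    as the full DP.
    """
    n = a.shape[0]
    m = b.shape[0]
    NEG = -10 ** 6
    width = 2 * band + 1
    best = 0
    bi = 0
    bo = 0
    for o in range(width):
        j = 0 + diag + o - band
        H[0, o] = 0 if 0 <= j <= m else NEG
        E[0, o] = NEG
        F[0, o] = NEG
        ptr[0, o] = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for o in range(width):
            j = i + diag + o - band
            if j < 0 or j > m:
                H[i, o] = NEG
                E[i, o] = NEG
                F[i, o] = NEG
                ptr[i, o] = 0
                continue
            if j == 0:
                H[i, o] = 0
                E[i, o] = NEG
                F[i, o] = NEG
                ptr[i, o] = 0
                continue
            # E: gap consuming b -> from (i, j-1) = offset o-1, same row
            if o - 1 >= 0:
                eo = H[i, o - 1] + go
                ee = E[i, o - 1] + ge
                if eo >= ee:
                    E[i, o] = eo
                    ptrE[i, o] = 1
                else:
                    E[i, o] = ee
                    ptrE[i, o] = 0
            else:
                E[i, o] = NEG
            # F: gap consuming a -> from (i-1, j) = offset o+1, row i-1
            if o + 1 < width:
                fo = H[i - 1, o + 1] + go
                fe = F[i - 1, o + 1] + ge
                if fo >= fe:
                    F[i, o] = fo
                    ptrF[i, o] = 1
                else:
                    F[i, o] = fe
                    ptrF[i, o] = 0
            else:
                F[i, o] = NEG
            # diagonal from (i-1, j-1) = same offset, row i-1
            if ai == b[j - 1] and ai < 4:
                s = H[i - 1, o] + match
            else:
                s = H[i - 1, o] + mismatch
            h = 0
            p = 0
            if s > h:
                h = s
                p = 1
            if E[i, o] > h:
                h = E[i, o]
                p = 2
            if F[i, o] > h:
                h = F[i, o]
                p = 3
            H[i, o] = h
            ptr[i, o] = p
            if h > best:
                best = h
                bi = i
                bo = o
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    i = bi
    o = bo
    matches = 0
    length = 0
    state = 0
    while i > 0:
        j = i + diag + o - band
        if j <= 0:
            break
        if state == 0:
            p = ptr[i, o]
            if p == 0:
                break
            if p == 1:
                length += 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    matches += 1
                i -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            length += 1
            opened = ptrE[i, o]
            o -= 1
            if opened == 1:
                state = 0
        else:
            length += 1
            opened = ptrF[i, o]
            i -= 1
            o += 1
            if opened == 1:
                state = 0
    j = i + diag + o - band
    return best, matches, length, i, bi, j, bi + diag + bo - band


@njit(cache=False)
def _batch_banded(mat, rc, lens, ii, jj, orient, diagc, k, band,
                  match, mismatch, go, ge):  # pragma: no cover
    npairs = ii.shape[0]
    scores = np.zeros(npairs, dtype=np.int32)
    matches = np.zeros(npairs, dtype=np.int32)
    lengths = np.zeros(npairs, dtype=np.int32)
    maxlen = mat.shape[1]
    width = 2 * band + 1
    H = np.zeros((maxlen + 1, width), dtype=np.int32)
    E = np.zeros((maxlen + 1, width), dtype=np.int32)
    F = np.zeros((maxlen + 1, width), dtype=np.int32)
    ptr = np.zeros((maxlen + 1, width), dtype=np.int8)
    ptrE = np.zeros((maxlen + 1, width), dtype=np.int8)
    ptrF = np.zeros((maxlen + 1, width), dtype=np.int8)
    for p in range(npairs):
        i = ii[p]
        j = jj[p]
        a = mat[i, : lens[i]]
        if orient[p] == 0:
            b = mat[j, : lens[j]]
            diag = diagc[p]
        else:
            b = rc[j, : lens[j]]
            diag = lens[j] - k - diagc[p]
        s, mt, ln, _, _, _, _ = _banded_gotoh(
            a, b, diag, band, H, E, F, ptr, ptrE, ptrF, match, mismatch, go, ge
        )
        scores[p] = s
        matches[p] = mt
        lengths[p] = ln
    return scores, matches, lengths


def _kmer_entries(sequences: list[str], k: int):
    """Flatten (canonical k-mer, read, position, strand-flag) over all reads."""
    kmers: list[np.ndarray] = []
    reads: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    flags: list[np.ndarray] = []
    for idx, seq in enumerate(sequences):
        codes = encode(seq)
        if len(codes) < k:
            continue
        fwd = _roll(codes, k)
        rcc = np.where(codes < 4, 3 - codes, 4).astype(np.uint8)[::-1]
        rev = _roll(rcc, k)[::-1]
        valid = _valid_windows(codes, k)
        if not valid.any():
            continue
        canon = np.minimum(fwd, rev)[valid]
        flag = (rev < fwd)[valid]
        pos = np.flatnonzero(valid)
        kmers.append(canon)
        reads.append(np.full(len(canon), idx, dtype=np.int32))
        poss.append(pos.astype(np.int32))
        flags.append(flag.astype(np.int8))
    if not kmers:
        empty = np.zeros(0, dtype=np.int64)
        return empty, empty.astype(np.int32), empty.astype(np.int32), empty.astype(np.int8)
    return (np.concatenate(kmers), np.concatenate(reads),
            np.concatenate(poss), np.concatenate(flags))


def pairwise_align(
    sequences: list[str],
    k: int = 12,
    min_shared: int = 1,
    band: int = 12,
    scoring: Scoring = Scoring(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Seeded strand-aware local alignment of every plausible pair.

    Candidate pairs share at least ``min_shared`` canonical ``k``-mers;
    each is aligned once, banded to ``band`` diagonals around the seed
    match, on the strand the seeds indicate.  Returns parallel arrays
    (i, j, orient, score, matches, length) with i < j, deterministic
    for fixed input.
    """
    n = len(sequences)
    km, rd, ps, fl = _kmer_entries(sequences, k)
    empty = np.zeros(0, dtype=np.int32)
    if len(km) == 0:
        return empty, empty, empty.astype(np.int8), empty, empty, empty
    order = np.argsort(km, kind="stable")
    km_s, rd_s, ps_s, fl_s = km[order], rd[order], ps[order], fl[order]
    boundaries = np.flatnonzero(np.diff(km_s)) + 1
    k_starts = np.concatenate(
        ([0], boundaries, [len(km_s)])
    ).astype(np.int64)
    group_of_sorted = np.zeros(len(km_s), dtype=np.int64)
    group_of_sorted[boundaries] = 1
    group_of_sorted = np.cumsum(group_of_sorted)
    # per-read view with group ids, in original (read-major) entry order
    group_orig = np.empty(len(km_s), dtype=np.int64)
    group_orig[order] = group_of_sorted
    read_bounds = np.searchsorted(rd, np.arange(n + 1))
    cnt_f = np.zeros(n, dtype=np.int32)
    cnt_r = np.zeros(n, dtype=np.int32)
    diag_f = np.zeros(n, dtype=np.int32)
    diag_r = np.zeros(n, dtype=np.int32)
    touched = np.zeros(n, dtype=np.int64)
    out_i, out_j, out_o, out_d = [], [], [], []
    for i in range(n):
        lo, hi = read_bounds[i], read_bounds[i + 1]
        if lo == hi:
            continue
        js, oo, dd, _ = _gather_for_read(
            i, group_orig[lo:hi], ps[lo:hi], fl[lo:hi],
            k_starts, rd_s, ps_s, fl_s,
            cnt_f, cnt_r, diag_f, diag_r, touched, min_shared,
        )
        if len(js):
            out_i.append(np.full(len(js), i, dtype=np.int32))
            out_j.append(js)
            out_o.append(oo)
            out_d.append(dd)
    if not out_i:
        return empty, empty, empty.astype(np.int8), empty, empty, empty
    ii = np.concatenate(out_i)
    jj = np.concatenate(out_j)
    oo = np.concatenate(out_o)
    dd = np.concatenate(out_d)
    maxlen = max(len(s) for s in sequences)
    mat = np.full((n, maxlen), 4, dtype=np.uint8)
    rc = np.full((n, maxlen), 4, dtype=np.uint8)
    lens = np.zeros(n, dtype=np.int64)
    for idx, s in enumerate(sequences):
        codes = encode(s)
        lens[idx] = len(codes)
        mat[idx, : len(codes)] = codes
        rc[idx, : len(codes)] = np.where(codes < 4, 3 - codes, 4)[::-1].astype(np.uint8)
    scores, matches, lengths = _batch_banded(
        mat, rc, lens, ii, jj, oo, dd, k, band,
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    return ii, jj, oo, scores, matches, lengths


@njit(cache=False)
def _gather_query(grp, pos, flag, k_starts, read_k, pos_k, flag_k,
                  cnt_f, cnt_r, diag_f, diag_r, touched,
                  min_shared):  # pragma: no cover
    """Reference partners sharing k-mers with one query (see _gather_for_read)."""
    ntouch = 0
    for e in range(grp.shape[0]):
        g = grp[e]
        p = pos[e]
        f = flag[e]
        for t in range(k_starts[g], k_starts[g + 1]):
            j = read_k[t]
            if cnt_f[j] == 0 and cnt_r[j] == 0:
                touched[ntouch] = j
                ntouch += 1
            if f == flag_k[t]:
                if cnt_f[j] == 0:
                    diag_f[j] = pos_k[t] - p
                cnt_f[j] += 1
            else:
                if cnt_r[j] == 0:
                    diag_r[j] = p + pos_k[t]
                cnt_r[j] += 1
    out_j = np.empty(ntouch, dtype=np.int32)
    out_o = np.empty(ntouch, dtype=np.int8)
    out_d = np.empty(ntouch, dtype=np.int32)
    m = 0
    for t in range(ntouch):
        j = touched[t]
        cf = cnt_f[j]
        cr = cnt_r[j]
        if cf + cr >= min_shared:
            out_j[m] = j
            if cf >= cr:
                out_o[m] = 0
                out_d[m] = diag_f[j]
            else:
                out_o[m] = 1
                out_d[m] = diag_r[j]
            m += 1
        cnt_f[j] = 0
        cnt_r[j] = 0
    return out_j[:m], out_o[:m], out_d[:m]


@njit(cache=False)
def _batch_banded_qr(qmat, qlens, rmat, rrc, rlens, qq, rr, orient, diagc,
                     k, band, match, mismatch, go, ge):  # pragma: no cover
    npairs = qq.shape[0]
    scores = np.zeros(npairs, dtype=np.int32)
    matches = np.zeros(npairs, dtype=np.int32)
    lengths = np.zeros(npairs, dtype=np.int32)
    maxq = qmat.shape[1]
    width = 2 * band + 1
    H = np.zeros((maxq + 1, width), dtype=np.int32)
    E = np.zeros((maxq + 1, width), dtype=np.int32)
    F = np.zeros((maxq + 1, width), dtype=np.int32)
    ptr = np.zeros((maxq + 1, width), dtype=np.int8)
    ptrE = np.zeros((maxq + 1, width), dtype=np.int8)
    ptrF = np.zeros((maxq + 1, width), dtype=np.int8)
    for p in range(npairs):
        q = qq[p]
        r = rr[p]
        a = qmat[q, : qlens[q]]
        if orient[p] == 0:
            b = rmat[r, : rlens[r]]
            diag = diagc[p]
        else:
            b = rrc[r, : rlens[r]]
            diag = rlens[r] - k - diagc[p]
        s, mt, ln, _, _, _, _ = _banded_gotoh(
            a, b, diag, band, H, E, F, ptr, ptrE, ptrF, match, mismatch, go, ge
        )
        scores[p] = s
        matches[p] = mt
        lengths[p] = ln
    return scores, matches, lengths


def _pack(sequences: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    maxlen = max(len(s) for s in sequences)
    mat = np.full((len(sequences), maxlen), 4, dtype=np.uint8)
    rc = np.full((len(sequences), maxlen), 4, dtype=np.uint8)
    lens = np.zeros(len(sequences), dtype=np.int64)
    for i, s in enumerate(sequences):
        codes = encode(s)
        lens[i] = len(codes)
        mat[i, : len(codes)] = codes
        rc[i, : len(codes)] = np.where(codes < 4, 3 - codes, 4)[::-1].astype(np.uint8)
    return mat, rc, lens


def map_candidates(
    queries: list[str],
    refs: list[str],
    k: int = 12,
    min_shared: int = 1,
    band: int = 12,
    scoring: Scoring = Scoring(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Seeded banded alignment of every query against its candidate refs.

    Like :func:`pairwise_align` but asymmetric: each query is aligned
    to every reference it shares canonical k-mers with, on the strand
    and diagonal the seeds indicate.  Returns parallel arrays (query,
    ref, orient, score, matches, length).
    """
    nq, nr = len(queries), len(refs)
    empty = np.zeros(0, dtype=np.int32)
    if nq == 0 or nr == 0:
        return empty, empty, empty.astype(np.int8), empty, empty, empty
    rkm, rrd, rps, rfl = _kmer_entries(refs, k)
    if len(rkm) == 0:
        return empty, empty, empty.astype(np.int8), empty, empty, empty
    order = np.argsort(rkm, kind="stable")
    rkm_s, rrd_s, rps_s, rfl_s = rkm[order], rrd[order], rps[order], rfl[order]
    boundaries = np.flatnonzero(np.diff(rkm_s)) + 1
    k_starts = np.concatenate(([0], boundaries, [len(rkm_s)])).astype(np.int64)
    uniq_vals = rkm_s[np.concatenate(([0], boundaries))]
    qkm, qrd, qps, qfl = _kmer_entries(queries, k)
    if len(qkm) == 0:
        return empty, empty, empty.astype(np.int8), empty, empty, empty
    read_bounds = np.searchsorted(qrd, np.arange(nq + 1))
    cnt_f = np.zeros(nr, dtype=np.int32)
    cnt_r = np.zeros(nr, dtype=np.int32)
    diag_f = np.zeros(nr, dtype=np.int32)
    diag_r = np.zeros(nr, dtype=np.int32)
    touched = np.zeros(nr, dtype=np.int64)
    out_q, out_r, out_o, out_d = [], [], [], []
    for q in range(nq):
        lo, hi = read_bounds[q], read_bounds[q + 1]
        if lo == hi:
            continue
        g = np.searchsorted(uniq_vals, qkm[lo:hi])
        g = np.minimum(g, len(uniq_vals) - 1)
        present = uniq_vals[g] == qkm[lo:hi]
        if not present.any():
            continue
        rs, oo, dd = _gather_query(
            g[present], qps[lo:hi][present], qfl[lo:hi][present],
            k_starts, rrd_s, rps_s, rfl_s,
            cnt_f, cnt_r, diag_f, diag_r, touched, min_shared,
        )
        if len(rs):
            out_q.append(np.full(len(rs), q, dtype=np.int32))
            out_r.append(rs)
            out_o.append(oo)
            out_d.append(dd)
    if not out_q:
        return empty, empty, empty.astype(np.int8), empty, empty, empty
    qq = np.concatenate(out_q)
    rr = np.concatenate(out_r)
    oo = np.concatenate(out_o)
    dd = np.concatenate(out_d)
    qmat, _, qlens = _pack(queries)
    rmat, rrc, rlens = _pack(refs)
    scores, matches, lengths = _batch_banded_qr(
        qmat, qlens, rmat, rrc, rlens, qq, rr, oo, dd, k, band,
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    return qq, rr, oo, scores, matches, lengths


class KmerIndex:
    """Inverted index from canonical k-mer to the sequences containing it."""

    def __init__(self, sequences: list[str], k: int = 12):
        self.k = k
        self.index: dict[int, list[int]] = {}
        for idx, seq in enumerate(sequences):
            for kmer in canonical_kmers(seq, k):
                self.index.setdefault(kmer, []).append(idx)

    def candidates(self, seq: str, min_shared: int = 1) -> list[int]:
        """Indices sharing >= min_shared canonical k-mers with ``seq``."""
        counts: dict[int, int] = {}
        for kmer in canonical_kmers(seq, self.k):
            for idx in self.index.get(kmer, ()):
                counts[idx] = counts.get(idx, 0) + 1
        return sorted(i for i, c in counts.items() if c >= min_shared)

    def candidate_pairs(self, min_shared: int = 1) -> list[tuple[int, int]]:
        """All unordered index pairs sharing >= min_shared canonical k-mers."""
        counts: dict[tuple[int, int], int] = {}
        for members in self.index.values():
            if len(members) < 2:
                continue
            for x in range(len(members)):
                mx = members[x]
                for y in range(x + 1, len(members)):
                    my = members[y]
                    if mx == my:
                        continue
                    key = (mx, my) if mx < my else (my, mx)
                    counts[key] = counts.get(key, 0) + 1
        return sorted(p for p, c in counts.items() if c >= min_shared)
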