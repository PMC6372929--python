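"""Numba kernels: 2-bit sequence codes, minimizer extraction, affine-gap
banded Smith-Waterman with traceback.

Bases are encoded A=0, C=1, G=2, T=3, N(or anything else)=4.  Code 4 never
scores as a match.  The alignment kernel works in band coordinates: cell
(i, j) of the full DP matrix is stored at column d = j - i - (c - b), so a
diagonal move stays in the same column, a query gap (up) moves one column
right in the previous row, and a target gap (left) one column left in the
same row.  A gap of length L costs gap_open + L * gap_extend (minimap2
convention), so the thresholds quoted against minimap2 output transfer.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.int32(-(10**9) // 2)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A0 C1 G2 T3, other 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1].copy()


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


@njit(cache=True, inline="always")
def _mix64(x: np.uint64) -> np.uint64:
    # splitmix64 finalizer: an invertible mix so window minima are spread
    # uniformly over k-mer space.
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


@njit(cache=True)
def minimizer_scan(codes: np.ndarray, k: int, w: int):
    """Window-minimum minimizers of the forward strand.

    Returns (positions, kmers): for every window of w consecutive k-mers the
    position whose hashed k-mer is minimal, deduplicated.  K-mers containing
    code >= 4 are invalid and never selected.
    """
    n = codes.shape[0]
    nk = n - k + 1
    out_pos = np.empty(max(nk, 0), dtype=np.int64)
    out_kmer = np.empty(max(nk, 0), dtype=np.uint64)
    cnt = 0
    if nk <= 0:
        return out_pos[:0], out_kmer[:0]
    mask = np.uint64((1 << (2 * k)) - 1)
    hashes = np.empty(nk, dtype=np.uint64)
    kmers = np.empty(nk, dtype=np.uint64)
    valid = np.zeros(nk, dtype=np.bool_)
    km = np.uint64(0)
    last_bad = -1
    for i in range(n):
        c = codes[i]
        if c >= 4:
            last_bad = i
            km = np.uint64(0)
        else:
            km = ((km << np.uint64(2)) | np.uint64(c)) & mask
        p = i - k + 1
        if p >= 0:
            kmers[p] = km
            if last_bad < p:
                valid[p] = True
                hashes[p] = _mix64(km)
            else:
                hashes[p] = np.uint64(0xFFFFFFFFFFFFFFFF)
    nwin = nk - w + 1
    if nwin <= 0:
        # sequence shorter than one full window: take the single best k-mer
        best = -1
        for p in range(nk):
            if valid[p] and (best < 0 or hashes[p] < hashes[best]):
                best = p
        if best >= 0:
            out_pos[0] = best
            out_kmer[0] = kmers[best]
            cnt = 1
        return out_pos[:cnt], out_kmer[:cnt]
    prev = -1
    for s in range(nwin):
        best = -1
        for p in range(s, s + w):
            if valid[p] and (best < 0 or hashes[p] < hashes[best]):
                best = p
        if best >= 0 and best != prev:
            out_pos[cnt] = best
            out_kmer[cnt] = kmers[best]
            cnt += 1
            prev = best
    return out_pos[:cnt], out_kmer[:cnt]


# traceback codes (low 2 bits): 0 stop, 1 diagonal, 2 left (target gap),
# 3 up (query gap); bit 2: left gap was an extension; bit 3: up gap was an
# extension.
@njit(cache=True)
def banded_sw(
    q: np.ndarray,
    t: np.ndarray,
    c: int,
    b: int,
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
    z_drop: int,
):
    """Local affine-gap alignment of q against t within band |j - i - c| <= b.

    All penalty arguments are magnitudes (positive).  Returns
    (score, q_start, q_end, t_start, t_end, n_match, block_length) with
    half-open coordinates; score 0 means no positive-scoring alignment.
    """
    n = q.shape[0]
    m = t.shape[0]
    W = 2 * b + 1
    lo = c - b  # j - i offset of band column 0
    goe = gap_open + gap_extend

    Hp = np.zeros(W, dtype=np.int32)  # H of previous row
    Fp = np.full(W, NEG_INF, dtype=np.int32)  # F (query-gap) of previous row
    Hc = np.zeros(W, dtype=np.int32)
    Fc = np.full(W, NEG_INF, dtype=np.int32)
    tb = np.zeros((n + 1, W), dtype=np.uint8)

    # row 0: j = lo + d must be valid (>= 0) for H=0 start cells
    for d in range(W):
        j = lo + d
        if j < 0 or j > m:
            Hp[d] = NEG_INF

    best = np.int32(0)
    bi = 0
    bd = 0
    for i in range(1, n + 1):
        qc = q[i - 1]
        e = NEG_INF  # E (target-gap) running value within the row
        rowmax = NEG_INF
        for d in range(W):
            j = i + lo + d
            if j < 0 or j > m:
                Hc[d] = NEG_INF
                Fc[d] = NEG_INF
                continue
            if j == 0:
                Hc[d] = 0
                Fc[d] = NEG_INF
                e = NEG_INF
                if 0 > rowmax:
                    rowmax = 0
                continue
            # E: gap in target (consume t[j-1]), from the left cell (d-1)
            if d > 0:
                h_left = Hc[d - 1]
                e_open = h_left - goe
                e_ext = e - gap_extend
                if e_ext > e_open:
                    e = e_ext
                    e_from_e = True
                else:
                    e = e_open
                    e_from_e = False
            else:
                e = NEG_INF
                e_from_e = False
            # F: gap in query (consume q[i-1]), from the upper cell (d+1 prev row)
            if d + 1 < W:
                f_open = Hp[d + 1] - goe
                f_ext = Fp[d + 1] - gap_extend
                if f_ext > f_open:
                    f = f_ext
                    f_from_f = True
                else:
                    f = f_open
                    f_from_f = False
            else:
                f = NEG_INF
                f_from_f = False
            Fc[d] = f
            tc = t[j - 1]
            if qc == tc and qc < 4:
                diag = Hp[d] + match
            else:
                diag = Hp[d] - mismatch
            h = diag
            code = np.uint8(1)
            if e > h:
                h = e
                code = np.uint8(2)
            if f > h:
                h = f
                code = np.uint8(3)
            if h <= 0:
                h = 0
                code = np.uint8(0)
            flags = np.uint8(0)
            if e_from_e:
                flags |= np.uint8(4)
            if f_from_f:
                flags |= np.uint8(8)
            tb[i, d] = code | flags
            Hc[d] = h
            if h > rowmax:
                rowmax = h
            if h > best:
                best = h
                bi = i
                bd = d
        # z-drop: once an alignment has been seen, stop when the whole row
        # falls too far below the running maximum.
        if best > z_drop and rowmax < best - z_drop and i > bi:
            break
        Hp, Hc = Hc, Hp
        Fp, Fc = Fc, Fp

    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0

    # traceback: explicit H/E/F state machine so that gap runs are followed
    # through the E/F layers rather than re-reading H decisions mid-run.
    i = bi
    d = bd
    n_match = 0
    n_cols = 0
    state = 0  # 0 = H, 1 = E (target gap, left), 2 = F (query gap, up)
    while i >= 0 and 0 <= d < W:
        cell = tb[i, d]
        if state == 0:
            code = cell & np.uint8(3)
            if code == 0:
                break
            if code == 1:
                j = i + lo + d
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    n_match += 1
                n_cols += 1
                i -= 1
            elif code == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            # E(i, d) consumed t[j-1]; it came from the left neighbour, as an
            # E extension if flag bit 2 is set, else opening from H.
            n_cols += 1
            ext = cell & np.uint8(4)
            d -= 1
            state = 1 if ext else 0
        else:
            n_cols += 1
            ext = cell & np.uint8(8)
            i -= 1
            d += 1
            state = 2 if ext else 0
    q_start = i
    t_start = i + lo + d
    q_end = bi
    t_end = bi + lo + bd
    return int(best), q_start, q_end, t_start, t_end, n_match, n_cols
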