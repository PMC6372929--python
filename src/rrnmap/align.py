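"""Read-to-reference mapping: minimizer seeding, diagonal chaining, banded
affine-gap extension with z-drop, Smith-Waterman-style AS scores.

Each read is mapped on both strands.  Minimizer matches against the indexed
references are grouped per (reference, strand) into co-linear diagonal
clusters; the strongest clusters are extended with a banded local
dynamic-programming alignment whose score is the hit's AS.  ``block_length``
counts all alignment columns including gaps (the PAF column-11 convention),
so the downstream block thresholds match what a minimap2-based workflow
would see.  The ``smith_waterman`` function is the exact full-matrix
reference used as an oracle in tests and on small inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .refdb import ReferenceDB


@dataclass(frozen=True)
class AlignParams:
    k: int = 15
    w: int = 10
    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2
    z_drop: int = 70
    max_secondary: int = 5
    band_width: int | None = None  # None: adaptive max(100, 0.05 * read length)
    min_chain_anchors: int = 3
    max_candidates: int = 6
    min_hit_score: int = 50
    chain_diag_tol: int = 100

    def __post_init__(self):
        if self.k < 8:
            raise ValueError("k must be >= 8")
        if self.match <= 0 or self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("match must be > 0; mismatch/gap penalties < 0")
        if self.z_drop <= 0:
            raise ValueError("z_drop must be > 0")

    def band_for(self, read_len: int) -> int:
        if self.band_width is not None:
            return self.band_width
        return max(100, int(0.05 * read_len))


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a read against a reference.

    Coordinates are 0-based half-open; read coordinates always refer to the
    forward (as-sequenced) read, regardless of strand.
    """

    read_id: str
    ref_id: str
    strand: str
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    block_length: int  # alignment columns including gaps
    n_match: int
    as_score: int

    @property
    def identity(self) -> float:
        return self.n_match / self.block_length


@dataclass
class LocalAlignment:
    score: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    n_match: int
    block_length: int

    @property
    def identity(self) -> float:
        return self.n_match / self.block_length if self.block_length else 0.0


def smith_waterman(
    query: str, target: str, params: AlignParams = AlignParams()
) -> LocalAlignment:
    """Exact affine-gap local alignment (full DP matrix).

    O(|q|*|t|) reference implementation; a gap of length L costs
    |gap_open| + L * |gap_extend|.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    q = K.encode(query)
    t = K.encode(target)
    n, m = len(q), len(t)
    c = (m - n) // 2
    b = (n + m) // 2 + 2
    s, qs, qe, ts, te, nm, nc = K.banded_sw(
        q, t, c, b, params.match, -params.mismatch, -params.gap_open,
        -params.gap_extend, 2**30,
    )
    return LocalAlignment(s, qs, qe, ts, te, nm, nc)


class MinimizerIndex:
    """Minimizer index over the forward strands of a reference DB."""

    def __init__(self, db: ReferenceDB, params: AlignParams = AlignParams()):
        if len(db) == 0:
            raise ValueError("cannot index an empty reference DB")
        self.db = db
        self.params = params
        self.ref_ids = [r.ref_id for r in db.records]
        self.ref_codes = [K.encode(r.sequence) for r in db.records]
        self.seeds: dict[int, list[tuple[int, int]]] = {}
        self.n_minimizers_per_ref: list[int] = []
        for ridx, codes in enumerate(self.ref_codes):
            pos, kmers = K.minimizer_scan(codes, params.k, params.w)
            self.n_minimizers_per_ref.append(len(pos))
            if len(pos) == 0:
                warnings.warn(
                    f"reference {self.ref_ids[ridx]} shorter than k={params.k}: "
                    "no minimizers indexed",
                    stacklevel=2,
                )
            for p, km in zip(pos, kmers):
                self.seeds.setdefault(int(km), []).append((ridx, int(p)))


def build_index(db: ReferenceDB, params: AlignParams = AlignParams()) -> MinimizerIndex:
    return MinimizerIndex(db, params)


@dataclass
class _Cluster:
    ridx: int
    strand: str
    n_anchors: int
    read_lo: int
    read_hi: int
    ref_lo: int
    ref_hi: int
    diag: int


def _clusters_for_strand(index, codes, strand, params):
    pos, kmers = K.minimizer_scan(codes, params.k, params.w)
    anchors: dict[int, list[tuple[int, int]]] = {}
    for p, km in zip(pos, kmers):
        hits = index.seeds.get(int(km))
        if not hits:
            continue
        for ridx, rp in hits:
            anchors.setdefault(ridx, []).append((rp - int(p), int(p), rp))
    out = []
    for ridx, ancs in anchors.items():
        ancs.sort()
        start = 0
        for i in range(1, len(ancs) + 1):
            if i == len(ancs) or ancs[i][0] - ancs[i - 1][0] > params.chain_diag_tol:
                group = ancs[start:i]
                start = i
                if len(group) < params.min_chain_anchors:
                    continue
                rps = [a[1] for a in group]
                tps = [a[2] for a in group]
                diags = [a[0] for a in group]
                out.append(
                    _Cluster(
                        ridx=ridx,
                        strand=strand,
                        n_anchors=len(group),
                        read_lo=min(rps),
                        read_hi=max(rps) + params.k,
                        ref_lo=min(tps),
                        ref_hi=max(tps) + params.k,
                        diag=int(np.median(diags)),
                    )
                )
    return out


def _extend_cluster(index, codes, cl: _Cluster, params: AlignParams):
    """Banded local extension of one chain; returns kernel tuple + window start."""
    band = params.band_for(len(codes))
    ref = index.ref_codes[cl.ridx]
    # target window: allow the alignment to run to both read ends plus slack
    ts = max(0, cl.ref_lo - cl.read_lo - band)
    te = min(len(ref), cl.ref_hi + (len(codes) - cl.read_hi) + band)
    window = ref[ts:te]
    c = cl.diag - ts
    res = K.banded_sw(
        codes,
        window,
        c,
        band,
        params.match,
        -params.mismatch,
        -params.gap_open,
        -params.gap_extend,
        params.z_drop,
    )
    return res, ts


def map_read(index: MinimizerIndex, read, params: AlignParams | None = None) -> list[AlignmentHit]:
    """Map one read against the index; hits sorted by AS descending.

    Both strands are searched; chimeric reads can return hits on disjoint
    read intervals.  At most ``max_secondary + 1`` hits are reported.
    """
    params = params or index.params
    fwd = K.encode(read.sequence)
    if len(fwd) < params.k:
        return []
    rev = K.revcomp_codes(fwd)
    clusters = _clusters_for_strand(index, fwd, "+", params) + _clusters_for_strand(
        index, rev, "-", params
    )
    clusters.sort(key=lambda c: (-c.n_anchors, index.ref_ids[c.ridx], c.ref_lo))
    # redundancy filter: keep at most 2 clusters per (ref, strand) and skip
    # clusters mostly covered by a stronger kept cluster on the same target
    kept: list[_Cluster] = []
    per_target: dict[tuple[int, str], int] = {}
    for cl in clusters:
        key = (cl.ridx, cl.strand)
        if per_target.get(key, 0) >= 2:
            continue
        redundant = False
        for other in kept:
            if (other.ridx, other.strand) != key:
                continue
            ov = min(cl.read_hi, other.read_hi) - max(cl.read_lo, other.read_lo)
            if ov > 0.5 * (cl.read_hi - cl.read_lo):
                redundant = True
                break
        if redundant:
            continue
        kept.append(cl)
        per_target[key] = per_target.get(key, 0) + 1
        if len(kept) >= params.max_candidates:
            break

    L = len(fwd)
    hits: list[AlignmentHit] = []
    for cl in kept:
        codes = fwd if cl.strand == "+" else rev
        (score, qs, qe, tts, tte, nm, nc), ts = _extend_cluster(index, codes, cl, params)
        if score < params.min_hit_score:
            continue
        if cl.strand == "+":
            r0, r1 = qs, qe
        else:
            r0, r1 = L - qe, L - qs
        hits.append(
            AlignmentHit(
                read_id=read.read_id,
                ref_id=index.ref_ids[cl.ridx],
                strand=cl.strand,
                read_start=r0,
                read_end=r1,
                ref_start=ts + tts,
                ref_end=ts + tte,
                block_length=nc,
                n_match=nm,
                as_score=score,
            )
        )
    # drop duplicate hits on the same reference covering the same read span
    hits.sort(key=lambda h: (-h.as_score, h.ref_id, h.ref_start))
    dedup: list[AlignmentHit] = []
    for h in hits:
        dup = False
        for g in dedup:
            if g.ref_id != h.ref_id:
                continue
            ov = min(h.read_end, g.read_end) - max(h.read_start, g.read_start)
            if ov > 0.8 * (h.read_end - h.read_start):
                dup = True
                break
        if not dup:
            dedup.append(h)
    return dedup[: params.max_secondary + 1]


def map_reads(
    index: MinimizerIndex, reads, params: AlignParams | None = None
) -> dict[str, list[AlignmentHit]]:
    """Map a collection of reads; returns read_id -> hits (possibly empty)."""
    return {r.read_id: map_read(index, r, params) for r in reads}


def hits_to_paf(hits: list[AlignmentHit], db: ReferenceDB, read_lengths: dict[str, int]) -> pd.DataFrame:
    """PAF-style hit table (core columns) with an AS:i tag column."""
    ref_len = {r.ref_id: r.length for r in db.records}
    rows = []
    for h in hits:
        rows.append(
            {
                "read_id": h.read_id,
                "read_length": read_lengths[h.read_id],
                "read_start": h.read_start,
                "read_end": h.read_end,
                "strand": h.strand,
                "ref_id": h.ref_id,
                "ref_length": ref_len[h.ref_id],
                "ref_start": h.ref_start,
                "ref_end": h.ref_end,
                "n_match": h.n_match,
                "block_length": h.block_length,
                "mapq": 255,
                "AS": h.as_score,
            }
        )
    return pd.DataFrame(rows)
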