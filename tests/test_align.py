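"""Aligner: Smith-Waterman oracle agreement, minimizer index, mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rrnmap as rm
from rrnmap import simulate as S
from rrnmap._kernels import decode, encode, minimizer_scan, revcomp_codes, _mix64
from rrnmap.align import (
    AlignParams,
    MinimizerIndex,
    build_index,
    map_read,
    smith_waterman,
)
from rrnmap.io import Read
from rrnmap.refdb import ReferenceRecord, build_db

MATCH, MISMATCH, GO, GE = 2, -4, -4, -2


def sw_oracle(a: str, b: str) -> int:
    """Plain-python affine-gap local alignment score (gap of L costs 4+2L)."""
    NEG = -(10**9)
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + GO + GE, E[i][j - 1] + GE)
            F[i][j] = max(H[i - 1][j] + GO + GE, F[i - 1][j] + GE)
            sc = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            H[i][j] = max(0, H[i - 1][j - 1] + sc, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


DNA = st.text(alphabet="ACGT", min_size=1, max_size=20)


def test_sw_perfect_match_and_local_example():
    assert smith_waterman("ACGTACGTAC", "ACGTACGTAC").score == 20
    # the best local alignment of ACGT vs AGGT is the GT/GT suffix: score 4
    assert smith_waterman("ACGT", "AGGT").score == 4


@settings(max_examples=150, deadline=None, derandomize=True)
@given(DNA, DNA)
def test_sw_agrees_with_python_oracle(a, b):
    got = smith_waterman(a, b)
    assert got.score == sw_oracle(a, b)
    assert got.score >= 0
    # reported interval is consistent with the path
    assert got.block_length >= got.query_end - got.query_start
    assert got.block_length >= got.target_end - got.target_start


def test_sw_agrees_with_biopython_on_random_pairs():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GO + GE
    aligner.extend_gap_score = GE
    rng = np.random.default_rng(5)
    for _ in range(100):
        a = decode(rng.integers(0, 4, rng.integers(10, 120)).astype(np.uint8))
        b = decode(rng.integers(0, 4, rng.integers(10, 120)).astype(np.uint8))
        assert smith_waterman(a, b).score == aligner.score(a, b)


def test_n_bases_never_match():
    got = smith_waterman("ACGTNNNNACGT", "ACGTNNNNACGT")
    # the two ACGT blocks can be bridged (8 matches) but Ns score as mismatches
    assert got.n_match <= 8


# --- minimizer index --------------------------------------------------------

def _naive_minimizers(codes, k, w):
    """Direct-scan oracle: hash every k-mer, take each window's argmin."""
    n = len(codes)
    hashes, valid, kmers = [], [], []
    for p in range(n - k + 1):
        window = codes[p : p + k]
        if (window >= 4).any():
            valid.append(False)
            hashes.append(None)
            kmers.append(None)
            continue
        km = 0
        for c in window:
            km = (km << 2) | int(c)
        valid.append(True)
        hashes.append(int(_mix64(np.uint64(km))))
        kmers.append(km)
    picks = set()
    nk = n - k + 1
    for s in range(max(nk - w + 1, 0)):
        cands = [(hashes[p], p) for p in range(s, s + w) if valid[p]]
        if cands:
            picks.add(min(cands)[1])
    return picks


def test_minimizer_scan_matches_direct_scan_oracle():
    rng = np.random.default_rng(3)
    codes = rng.integers(0, 4, 800).astype(np.uint8)
    codes[100:104] = 4  # an N run
    pos, kmers = minimizer_scan(codes, 15, 10)
    assert set(pos.tolist()) == _naive_minimizers(codes, 15, 10)


def test_minimizer_density_close_to_two_over_w_plus_one():
    rng = np.random.default_rng(9)
    L = 6000
    codes = rng.integers(0, 4, L).astype(np.uint8)
    pos, _ = minimizer_scan(codes, 15, 10)
    expected = 2 * L / 11
    assert abs(len(pos) - expected) < 0.15 * expected


def test_index_warns_when_k_exceeds_sequence(recwarn):
    tiny = ReferenceRecord("t", "T sp", "T", (("species", "T sp"),), "ACGTACGT")
    db = build_db([tiny], "16S")
    with pytest.warns(UserWarning, match="no minimizers"):
        idx = build_index(db, AlignParams(k=15, w=5))
    assert idx.n_minimizers_per_ref == [0]


def test_index_empty_db_is_error():
    with pytest.raises(ValueError, match="empty"):
        build_index(build_db([], "16S"), "16S")


def test_duplicate_records_index_identically(s16_db6):
    rec = s16_db6.records[0]
    twin = ReferenceRecord("twin", rec.species, rec.genus, rec.lineage, rec.sequence)
    db = build_db([rec, twin], "16S")
    idx = build_index(db)
    assert idx.n_minimizers_per_ref[0] == idx.n_minimizers_per_ref[1]


# --- mapping ----------------------------------------------------------------

@pytest.fixture(scope="module")
def small_index():
    """5 short references for exhaustive-oracle comparisons."""
    rng = np.random.default_rng(21)
    recs = [
        ReferenceRecord(
            f"S{i}", f"S{i} sp", f"S{i}",
            (("genus", f"S{i}"), ("species", f"S{i} sp")),
            decode(rng.integers(0, 4, 400).astype(np.uint8)),
        )
        for i in range(5)
    ]
    db = build_db(recs, "16S")
    params = AlignParams(min_hit_score=20, min_chain_anchors=2)
    return db, build_index(db, params), params


def test_map_read_matches_exhaustive_sw(small_index):
    """Reported AS equals full Smith-Waterman on the reported interval, and
    the top reference agrees with an exhaustive scan (>=99% over 200 reads)."""
    db, idx, params = small_index
    rng = np.random.default_rng(33)
    agree = checked = 0
    for t in range(200):
        src = db.records[rng.integers(0, 5)]
        L = int(rng.integers(100, 301))
        start = int(rng.integers(0, len(src.sequence) - L + 1))
        frag = src.sequence[start : start + L]
        read = Read(f"q{t}", frag)
        hits = map_read(idx, read, params)
        assert hits, "noiseless fragment must map"
        top = hits[0]
        # interval score check
        sub_q = frag[top.read_start : top.read_end]
        sub_t = db.get(top.ref_id).sequence[top.ref_start : top.ref_end]
        assert smith_waterman(sub_q, sub_t).score == top.as_score
        # exhaustive best-reference oracle
        best_ref = max(
            db.records, key=lambda r: (smith_waterman(frag, r.sequence).score, r.ref_id)
        )
        checked += 1
        agree += top.ref_id == best_ref.ref_id
    assert agree / checked >= 0.99


def test_top_hit_is_truth_reference_at_5pct_error(s16_db6):
    design = S.even_design(s16_db6.species, 60, "16S")
    reads, _ = S.simulate_reads(
        s16_db6, design, error=S.ErrorModel.from_accuracy(0.95), seed=51
    )
    idx = build_index(s16_db6)
    for r in reads:
        hits = map_read(idx, r)
        assert hits
        # exhaustive SW over every reference as oracle
        oriented = r.sequence if r.strand == "+" else decode(revcomp_codes(encode(r.sequence)))
        best = max(
            s16_db6.records,
            key=lambda rec: (smith_waterman(oriented, rec.sequence).score, rec.ref_id),
        )
        assert hits[0].ref_id == best.ref_id


def test_strand_symmetry(s16_db6):
    design = S.even_design(s16_db6.species, 20, "16S")
    reads, _ = S.simulate_reads(s16_db6, design, seed=61)
    idx = build_index(s16_db6)
    for r in reads[:10]:
        rc = decode(revcomp_codes(encode(r.sequence)))
        h1 = map_read(idx, Read(r.read_id, r.sequence))
        h2 = map_read(idx, Read(r.read_id, rc))
        assert sorted(h.as_score for h in h1) == sorted(h.as_score for h in h2)
        top1, top2 = h1[0], h2[0]
        assert top1.strand != top2.strand
        assert (top1.read_start, top1.read_end) == (
            len(r.sequence) - top2.read_end,
            len(r.sequence) - top2.read_start,
        )


def test_read_without_shared_kmers_maps_nowhere(small_index):
    _, idx, params = small_index
    assert map_read(idx, Read("q", "AT" * 60), params) == []


def test_median_top_as_antitone_in_error_rate(s16_db6):
    idx = build_index(s16_db6)
    design = S.even_design(s16_db6.species, 40, "16S")
    medians = []
    for acc in (1.0, 0.95, 0.89, 0.80):
        error = S.NOISELESS if acc == 1.0 else S.ErrorModel.from_accuracy(acc)
        reads, _ = S.simulate_reads(s16_db6, design, error=error, seed=71)
        tops = []
        for r in reads:
            hits = map_read(idx, r)
            if hits:
                tops.append(hits[0].as_score)
        medians.append(np.median(tops))
    assert all(a >= b for a, b in zip(medians, medians[1:]))


def test_hit_invariants(even_rrn_run):
    for hits in even_rrn_run.res.hits_by_read.values():
        for h in hits:
            assert 0 <= h.read_start < h.read_end <= even_rrn_run.res.read_lengths[h.read_id]
            assert h.block_length >= h.read_end - h.read_start
            assert 0 < h.identity <= 1
        assert [x.as_score for x in hits] == sorted(
            (x.as_score for x in hits), reverse=True
        )
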