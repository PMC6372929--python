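"""Simulator: determinism, error model calibration, designs, carryover."""

import io as _io

import numpy as np
import pytest
from scipy import stats

from rrnmap import simulate as S
from rrnmap._kernels import decode, encode, revcomp_codes
from rrnmap.align import smith_waterman


def _oriented(read):
    seq = read.sequence
    return seq if read.strand == "+" else decode(revcomp_codes(encode(seq)))


def _fastq_bytes(reads):
    buf = _io.StringIO()
    for r in reads:
        buf.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
    return buf.getvalue()


# --- reference synthesis ---------------------------------------------------

def test_reference_set_shape_and_determinism():
    db1 = S.synthesize_reference_set(8, "rrn", seed=5)
    db2 = S.synthesize_reference_set(8, "rrn", seed=5)
    assert db1.n_species == 8
    for r in db1.records:
        assert abs(r.length - 4300) < 4300 * 0.1
    assert [r.sequence for r in db1.records] == [r.sequence for r in db2.records]
    assert S.synthesize_reference_set(8, "rrn", seed=6).records[2].sequence != db1.records[2].sequence


def test_close_pair_identity_by_global_alignment():
    from Bio import Align

    db = S.synthesize_reference_set(6, "16S", close_pair_identity=0.97, seed=5)
    a = db.refs_of_species(db.close_pair[0])[0].sequence
    b = db.refs_of_species(db.close_pair[1])[0].sequence
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -2
    aln = aligner.align(a, b)[0]
    matches = sum(
        x == y for seg_a, seg_b in zip(*aln.aligned)
        for x, y in zip(a[seg_a[0]:seg_a[1]], b[seg_b[0]:seg_b[1]])
    )
    identity = matches / max(len(a), len(b))
    assert identity == pytest.approx(0.97, abs=0.005)
    # the pair shares its genus, everyone else has a private one
    assert db.get("REF00").genus == db.get("REF01").genus


def test_infeasible_divergence_spec_rejected():
    with pytest.raises(ValueError, match="close_pair_identity"):
        S.synthesize_reference_set(4, "16S", close_pair_identity=0.3, seed=1)
    with pytest.raises(ValueError):
        S.synthesize_reference_set(4, "16S", close_pair_identity=1.5, seed=1)


# --- error model -----------------------------------------------------------

def test_error_model_validation_and_expectation():
    m = S.ErrorModel()
    assert m.expected_identity == pytest.approx(
        (1 - 0.0275) * (1 - 0.055) / (1 + 0.0275)
    )
    with pytest.raises(ValueError):
        S.ErrorModel(0.5, 0.3, 0.3)
    solved = S.ErrorModel.from_accuracy(0.89)
    assert solved.expected_identity == pytest.approx(0.89, abs=1e-9)


def test_noiseless_reads_are_exact_substrings(s16_db6):
    design = S.even_design(s16_db6.species, 40, "16S")
    reads, truth = S.simulate_reads(s16_db6, design, error=S.NOISELESS, seed=3)
    for r in reads:
        ref = s16_db6.get(r.truth_ref_id).sequence
        assert _oriented(r) in ref


def test_mean_identity_matches_analytic_rate(s16_db6):
    design = S.even_design(s16_db6.species, 300, "16S")
    reads, truth = S.simulate_reads(s16_db6, design, seed=11)
    analytic = S.ErrorModel().expected_identity
    # generative alignment identity recorded by the simulator
    assert abs(truth["identity"].mean() - analytic) < 0.005
    # optimal realignment can only do better, and only slightly
    sw_ids = []
    for r in reads[:150]:
        ref = s16_db6.get(r.truth_ref_id).sequence
        sw_ids.append(smith_waterman(_oriented(r), ref).identity)
    assert analytic - 0.002 <= np.mean(sw_ids) <= analytic + 0.01


def test_chimera_rate_and_structure(rrn_db8):
    design = S.even_design(rrn_db8.species, 2000, "rrn")
    reads, truth = S.simulate_reads(rrn_db8, design, chimera_rate=0.05, seed=13)
    n_chim = int(truth["is_chimera"].sum())
    # binomial(2000, 0.05): mean 100, sd ~9.7; allow 4 sd
    assert abs(n_chim - 100) < 40
    for r in reads:
        if r.is_chimera:
            assert r.truth_ref_id2 and r.truth_ref_id2 != r.truth_ref_id
            sp2 = rrn_db8.get(r.truth_ref_id2).species
            assert sp2 != r.truth_species
        else:
            assert r.truth_ref_id2 == ""


def test_species_proportions_match_design_lln(rrn_db8):
    design = S.even_design(rrn_db8.species, 10000, "rrn")
    _, truth = S.simulate_reads(rrn_db8, design, seed=17)
    counts = truth["truth_species"].value_counts().reindex(rrn_db8.species).fillna(0)
    p = stats.chisquare(counts).pvalue
    assert p > 0.01


def test_missing_species_and_empty_design_are_errors(rrn_db8):
    with pytest.raises(ValueError, match="no members"):
        S.CommunityDesign([], "proportion", "rrn", 10)
    design = S.CommunityDesign([("Ghost sp", 1.0)], "proportion", "rrn", 10)
    with pytest.raises(ValueError, match="Ghost"):
        S.simulate_reads(rrn_db8, design, seed=1)


def test_same_seed_byte_identical_output(s16_db6):
    design = S.even_design(s16_db6.species, 100, "16S")
    r1, t1 = S.simulate_reads(s16_db6, design, chimera_rate=0.03, seed=23)
    r2, t2 = S.simulate_reads(s16_db6, design, chimera_rate=0.03, seed=23)
    assert _fastq_bytes(r1) == _fastq_bytes(r2)
    assert t1.to_csv(sep="\t", index=False) == t2.to_csv(sep="\t", index=False)
    r3, _ = S.simulate_reads(s16_db6, design, chimera_rate=0.03, seed=24)
    assert _fastq_bytes(r3) != _fastq_bytes(r1)


def test_staggered_design_levels(rrn_db8):
    db = S.synthesize_reference_set(20, "16S", seed=31)
    design = S.staggered_design(db.species, 20000, "16S")
    weights = sorted(w for _, w in design.members)
    assert weights[:5] == [1e3] * 5 and weights[-5:] == [1e6] * 5
    with pytest.raises(ValueError):
        S.staggered_design(db.species[:7], 100, "16S")


# --- carryover -------------------------------------------------------------

def test_inject_carryover_fraction_and_labels(s16_db6):
    design_a = S.even_design(s16_db6.species[:3], 9400, "16S")
    design_b = S.even_design(s16_db6.species[3:], 700, "16S")
    primary, _ = S.simulate_reads(s16_db6, design_a, error=S.NOISELESS, seed=41)
    pool, _ = S.simulate_reads(s16_db6, design_b, error=S.NOISELESS, seed=42)
    mixed = S.inject_carryover(primary, pool, 0.06, seed=43)
    contams = [r for r in mixed if r.is_carryover]
    assert len(contams) == 600  # 6% of 10,000
    assert len(mixed) == 10000
    # labels preserved bit-exact
    by_id = {r.read_id: r for r in pool}
    for c in contams:
        src = by_id[c.read_id.removeprefix("co_")]
        assert (c.sequence, c.truth_species, c.truth_ref_id, c.strand) == (
            src.sequence, src.truth_species, src.truth_ref_id, src.strand
        )
    # primaries keep their flags
    assert all(not r.is_carryover for r in mixed if not r.read_id.startswith("co_"))


def test_inject_carryover_edge_cases(s16_db6):
    design = S.even_design(s16_db6.species[:2], 50, "16S")
    primary, _ = S.simulate_reads(s16_db6, design, error=S.NOISELESS, seed=1)
    assert S.inject_carryover(primary, [], 0.0, seed=1) == primary
    with pytest.raises(ValueError):
        S.inject_carryover(primary, primary, 1.0, seed=1)
    with pytest.raises(ValueError, match="pool too small"):
        S.inject_carryover(primary, primary[:1], 0.5, seed=1)
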