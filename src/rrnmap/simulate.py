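"""Synthetic reference sets and nanopore-like amplicon reads with truth labels.

The generator stands in for the wet-lab side of the study designs the
pipeline is meant to analyse: a pure isolate, an even 8-species community,
a staggered community spanning 1e3-1e6 operon copies, and cross-run barcode
carryover at a few percent.

Reference architecture
----------------------
Real ribosomal markers interleave segments that are nearly invariant across
bacteria with hypervariable segments.  Synthetic references reproduce that:
a master template is split into alternating conserved and variable segments;
every species keeps the conserved segments (with a small per-species
substitution rate) and draws its variable segments independently.  This
matters for database-incompleteness experiments: reads from a species that
is missing from the database still seed short, low-scoring alignments in
conserved segments of other species, as real rRNA reads do, instead of
going silently unmapped.

One designated close-relative pair (species of the same genus at ~97%
overall identity, emulating the hardest real confusions within a genus) is
always present.

Error model
-----------
Errors are independent per-base substitution / insertion / deletion events.
For rates (s, i, d) the expected identity of the generative alignment is
(1 - d)(1 - s) / (1 + i).  The default split for ~89% read accuracy is
s=0.055, i=0.0275, d=0.0275.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernels as K
from .markers import Marker, get_marker
from .refdb import RANKS, ReferenceDB, ReferenceRecord


# ---------------------------------------------------------------------------
# error model


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base substitution / insertion / deletion rates."""

    sub_rate: float = 0.055
    ins_rate: float = 0.0275
    del_rate: float = 0.0275
    target_accuracy: float = 0.89

    def __post_init__(self):
        if min(self.sub_rate, self.ins_rate, self.del_rate) < 0:
            raise ValueError("error rates must be >= 0")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1:
            raise ValueError("total error rate must be < 1")

    @property
    def expected_identity(self) -> float:
        """Analytic identity (matches / alignment columns) of the generative alignment."""
        return (
            (1 - self.del_rate)
            * (1 - self.sub_rate)
            / (1 + self.ins_rate)
        )

    @classmethod
    def from_accuracy(cls, accuracy: float, sub_frac: float = 0.5) -> "ErrorModel":
        """Solve rates for a target identity with a sub:ins:del = 2:1:1 style split.

        ``sub_frac`` is the share of total errors that are substitutions; the
        remainder splits evenly between insertions and deletions.
        """
        if not 0 < accuracy < 1:
            raise ValueError("accuracy must be in (0, 1)")
        # with s = 2u, i = u, d = u (sub_frac=0.5):
        # (1-u)(1-2u) = acc (1+u)  ->  2u^2 - (3+acc) u + (1-acc) = 0
        if abs(sub_frac - 0.5) < 1e-12:
            a, b, c = 2.0, -(3.0 + accuracy), 1.0 - accuracy
            u = (-b - math.sqrt(b * b - 4 * a * c)) / (2 * a)
            return cls(2 * u, u, u, accuracy)
        from scipy.optimize import brentq

        def gap(total):
            s = sub_frac * total
            io = (1 - sub_frac) * total / 2
            return (1 - io) * (1 - s) / (1 + io) - accuracy

        total = brentq(gap, 1e-9, 0.99)
        s = sub_frac * total
        io = (1 - sub_frac) * total / 2
        return cls(s, io, io, accuracy)


NOISELESS = ErrorModel(0.0, 0.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# community designs


@dataclass
class CommunityDesign:
    """Mock community composition: members, weights and sequencing depth."""

    members: list[tuple[str, float]]
    weight_kind: str  # "operon_copies" | "proportion"
    marker: Marker
    n_reads: int

    def __post_init__(self):
        self.marker = get_marker(self.marker)
        if not self.members:
            raise ValueError("community design has no members")
        if any(w <= 0 for _, w in self.members):
            raise ValueError("member weights must be > 0")
        names = [s for s, _ in self.members]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species in design")
        if self.weight_kind == "proportion":
            total = sum(w for _, w in self.members)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportions sum to {total}, expected 1")
        elif self.weight_kind != "operon_copies":
            raise ValueError(f"unknown weight_kind {self.weight_kind!r}")

    @property
    def proportions(self) -> np.ndarray:
        w = np.array([x for _, x in self.members], dtype=float)
        return w / w.sum()


def even_design(species: list[str], n_reads: int, marker) -> CommunityDesign:
    """Equal-proportion community (Zymo-style even mock)."""
    p = 1.0 / len(species)
    return CommunityDesign([(s, p) for s in species], "proportion", marker, n_reads)


def staggered_design(
    species: list[str],
    n_reads: int,
    marker,
    copy_levels: tuple[float, ...] = (1e3, 1e4, 1e5, 1e6),
) -> CommunityDesign:
    """Staggered community: operon copies on a log grid, emulating designs
    whose member abundances span 1e3-1e6 copies.

    Species are assigned to the copy levels in blocks (len(species) must be a
    multiple of len(copy_levels); 20 species over 4 levels gives 5 per level).
    """
    if len(species) % len(copy_levels):
        raise ValueError("number of species must be a multiple of the level count")
    per = len(species) // len(copy_levels)
    members = [
        (s, copy_levels[i // per]) for i, s in enumerate(species)
    ]
    return CommunityDesign(members, "operon_copies", marker, n_reads)


def isolate_design(species: str, n_reads: int, marker) -> CommunityDesign:
    return CommunityDesign([(species, 1.0)], "proportion", marker, n_reads)


# ---------------------------------------------------------------------------
# synthetic reads


@dataclass
class SyntheticRead:
    read_id: str
    sequence: str
    quality: str
    truth_species: str
    truth_ref_id: str
    truth_ref_id2: str = ""  # secondary segment source for chimeras
    is_chimera: bool = False
    is_carryover: bool = False
    strand: str = "+"
    identity: float = 1.0  # generative-alignment identity to the template

    def __len__(self) -> int:
        return len(self.sequence)


_DEFAULT_QUAL_CHAR = chr(33 + 12)  # constant Q12 placeholder


def _lineage_for(i: int, n_classes: int, genus: str, species: str, klass: int):
    return (
        ("domain", "Bacteria"),
        ("phylum", f"Phylum{klass:02d}"),
        ("class", f"Class{klass:02d}"),
        ("order", f"Order{klass:02d}"),
        ("family", f"Family{i:02d}"),
        ("genus", genus),
        ("species", species),
    )


def _mutate_subs_exact(codes: np.ndarray, n_subs: int, rng) -> np.ndarray:
    out = codes.copy()
    pos = rng.choice(len(codes), size=n_subs, replace=False)
    out[pos] = (out[pos] + rng.integers(1, 4, size=n_subs)) % 4
    return out


def synthesize_reference_set(
    n_species: int,
    marker,
    close_pair_identity: float = 0.97,
    conserved_len: int = 150,
    variable_len: int = 80,
    conserved_divergence: float = 0.02,
    length_sd_frac: float = 0.01,
    n_classes: int = 3,
    seed: int = 0,
) -> ReferenceDB:
    """Generate a labelled reference DB with one designated close-relative pair.

    Species 0 and 1 form the pair (same genus and class, overall identity
    ``close_pair_identity``); remaining species share only the conserved
    segments.  Deterministic given ``seed``.  The pair is recorded on the
    returned DB as ``db.close_pair``.
    """
    marker = get_marker(marker)
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not 0 < close_pair_identity < 1:
        raise ValueError("close_pair_identity must be in (0, 1)")
    cfrac = conserved_len / (conserved_len + variable_len)
    c = conserved_divergence
    background = cfrac * ((1 - c) ** 2 + c * c / 3) + (1 - cfrac) * 0.25
    if close_pair_identity <= background:
        raise ValueError(
            f"close_pair_identity {close_pair_identity} not above background "
            f"identity ~{background:.3f}"
        )
    rng = np.random.default_rng(seed)
    L = int(round(marker.nominal_length * 1.02))
    master = rng.integers(0, 4, size=L).astype(np.uint8)
    # segment layout: conserved, variable, conserved, ...
    conserved_mask = np.zeros(L, dtype=bool)
    pos = 0
    while pos < L:
        conserved_mask[pos : pos + conserved_len] = True
        pos += conserved_len + variable_len
    var_idx = np.flatnonzero(~conserved_mask)
    cons_idx = np.flatnonzero(conserved_mask)

    records = []
    lengths = np.clip(
        np.round(
            rng.normal(marker.nominal_length, length_sd_frac * marker.nominal_length, n_species)
        ).astype(int),
        int(0.9 * marker.nominal_length),
        L,
    )
    seqs: list[np.ndarray] = []
    for i in range(n_species):
        if i == 1 and n_species > 1:
            base = seqs[0]
            n_subs = int(round((1 - close_pair_identity) * len(base)))
            seq = _mutate_subs_exact(base, n_subs, rng)
        else:
            seq = master.copy()
            # per-species drift in conserved segments
            n_sub_c = rng.binomial(len(cons_idx), conserved_divergence)
            if n_sub_c:
                p = rng.choice(cons_idx, size=n_sub_c, replace=False)
                seq[p] = (seq[p] + rng.integers(1, 4, size=n_sub_c)) % 4
            # fresh variable segments
            seq[var_idx] = rng.integers(0, 4, size=len(var_idx))
            seq = seq[: lengths[i]]
        seqs.append(seq)

    for i, seq in enumerate(seqs):
        klass = 0 if i == 1 else i % n_classes
        genus = "Genus00" if i == 1 else f"Genus{i:02d}"
        species = f"{genus} species{i:02d}"
        records.append(
            ReferenceRecord(
                ref_id=f"REF{i:02d}",
                species=species,
                genus=genus,
                lineage=_lineage_for(i, n_classes, genus, species, klass),
                sequence=K.decode(seq),
            )
        )
    db = ReferenceDB(records, marker)
    db.close_pair = (records[0].species, records[1].species) if n_species > 1 else None
    return db


def add_close_relatives(
    db: ReferenceDB,
    species: list[str],
    identity: float = 0.97,
    seed: int = 0,
) -> ReferenceDB:
    """Append a decoy relative (same genus, ``identity`` overall) for each
    listed species; used to salt databases with confusable references."""
    rng = np.random.default_rng(seed)
    new_records = list(db.records)
    for j, sp in enumerate(species):
        refs = db.refs_of_species(sp)
        if not refs:
            raise ValueError(f"species not in DB: {sp!r}")
        src = refs[0]
        codes = K.encode(src.sequence)
        n_subs = int(round((1 - identity) * len(codes)))
        seq = _mutate_subs_exact(codes, n_subs, rng)
        name = f"{src.genus} relative{j:02d}"
        lineage = tuple(
            (r, name if r == "species" else n) for r, n in src.lineage
        )
        new_records.append(
            ReferenceRecord(
                ref_id=f"REL{j:02d}",
                species=name,
                genus=src.genus,
                lineage=lineage,
                sequence=K.decode(seq),
            )
        )
    return ReferenceDB(new_records, db.marker)


def apply_errors(codes: np.ndarray, model: ErrorModel, rng):
    """Apply iid per-base deletion, substitution and insertion events.

    Returns (mutated codes, n_match, n_columns) of the generative alignment:
    matches are kept unsubstituted bases, columns count matches, mismatches,
    insertions and deletions.
    """
    n = len(codes)
    keep = rng.random(n) >= model.del_rate
    kept = codes[keep].astype(np.int64)
    sub = rng.random(len(kept)) < model.sub_rate
    nsub = int(sub.sum())
    if nsub:
        kept[sub] = (kept[sub] + rng.integers(1, 4, size=nsub)) % 4
    ins = rng.random(n) < model.ins_rate
    nins = int(ins.sum())
    n_match = int(keep.sum()) - nsub
    n_cols = n + nins  # kept + deleted + inserted columns
    if nins:
        kept_before = np.cumsum(keep) - keep  # kept bases strictly before pos
        idx = kept_before[ins]
        bases = rng.integers(0, 4, size=nins)
        kept = np.insert(kept, idx, bases)
    return kept.astype(np.uint8), n_match, n_cols


def simulate_reads(
    db: ReferenceDB,
    design: CommunityDesign,
    error: ErrorModel = ErrorModel(),
    length_sd_frac: float = 0.03,
    chimera_rate: float = 0.0,
    short_fragment_rate: float = 0.0,
    short_fragment_range: tuple[float, float] = (0.3, 0.8),
    seed: int = 0,
) -> tuple[list[SyntheticRead], pd.DataFrame]:
    """Simulate ``design.n_reads`` reads with truth labels.

    Per-species read counts are multinomial in the design proportions.
    Chimeras concatenate error-free segments from two distinct members before
    errors are applied; short fragments are truncated amplicons below the
    marker's window.  Deterministic given ``seed``.
    """
    for rate, name in ((chimera_rate, "chimera_rate"), (short_fragment_rate, "short_fragment_rate")):
        if not 0 <= rate < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    missing = [s for s, _ in design.members if not db.refs_of_species(s)]
    if missing:
        raise ValueError(f"design species missing from DB: {missing}")
    rng = np.random.default_rng(seed)
    marker = get_marker(design.marker)
    species_names = [s for s, _ in design.members]
    probs = design.proportions
    ref_codes = {r.ref_id: K.encode(r.sequence) for r in db.records}
    refs_by_species = {s: [r.ref_id for r in db.refs_of_species(s)] for s in species_names}

    sp_idx = rng.choice(len(species_names), size=design.n_reads, p=probs)
    noiseless = error.sub_rate == error.ins_rate == error.del_rate == 0

    def sample_segment(ref_id: str, length: int) -> np.ndarray:
        codes = ref_codes[ref_id]
        length = min(length, len(codes))
        start = rng.integers(0, len(codes) - length + 1)
        return codes[start : start + length]

    reads: list[SyntheticRead] = []
    for i in range(design.n_reads):
        sp = species_names[sp_idx[i]]
        ref_id = refs_by_species[sp][rng.integers(0, len(refs_by_species[sp]))]
        u = rng.random()
        ref_id2 = ""
        is_chimera = False
        if u < chimera_rate and len(species_names) > 1:
            is_chimera = True
            sp2 = sp
            while sp2 == sp:
                sp2 = species_names[rng.integers(0, len(species_names))]
            ref_id2 = refs_by_species[sp2][rng.integers(0, len(refs_by_species[sp2]))]
            total = int(round(rng.normal(marker.nominal_length, length_sd_frac * marker.nominal_length)))
            total = max(total, 200)
            frac = rng.uniform(0.3, 0.7)
            seg1 = sample_segment(ref_id, int(round(total * frac)))
            seg2 = sample_segment(ref_id2, total - int(round(total * frac)))
            template = np.concatenate([seg1, seg2])
        elif u < chimera_rate + short_fragment_rate:
            lo, hi = short_fragment_range
            length = int(round(rng.uniform(lo, hi) * marker.nominal_length))
            template = sample_segment(ref_id, max(length, 50))
        else:
            full = len(ref_codes[ref_id])
            target = int(round(rng.normal(full, length_sd_frac * full)))
            template = sample_segment(ref_id, max(min(target, full), 50))
        if noiseless:
            seq, gen_identity = template, 1.0
        else:
            seq, n_match, n_cols = apply_errors(template, error, rng)
            gen_identity = n_match / n_cols
        strand = "+"
        if rng.random() < 0.5:
            strand = "-"
            seq = K.revcomp_codes(seq)
        reads.append(
            SyntheticRead(
                read_id=f"read{i:06d}",
                sequence=K.decode(seq),
                quality=_DEFAULT_QUAL_CHAR * len(seq),
                truth_species=sp,
                truth_ref_id=ref_id,
                truth_ref_id2=ref_id2,
                is_chimera=is_chimera,
                strand=strand,
                identity=gen_identity,
            )
        )
    return reads, truth_table(reads)


def truth_table(reads: list[SyntheticRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "truth_species": [r.truth_species for r in reads],
            "truth_ref_id": [r.truth_ref_id for r in reads],
            "truth_ref_id2": [r.truth_ref_id2 for r in reads],
            "is_chimera": [r.is_chimera for r in reads],
            "is_carryover": [r.is_carryover for r in reads],
            "strand": [r.strand for r in reads],
            "identity": [r.identity for r in reads],
        }
    )


def inject_carryover(
    primary_reads: list[SyntheticRead],
    contaminant_reads: list[SyntheticRead],
    fraction: float,
    seed: int = 0,
) -> list[SyntheticRead]:
    """Mix contaminant reads into a run so they form ``fraction`` of the total.

    Emulates cross-run barcode carryover; contaminants are flagged
    ``is_carryover=True`` and renamed with a ``co`` prefix to keep read ids
    unique.  Truth labels are otherwise preserved.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return list(primary_reads)
    rng = np.random.default_rng(seed)
    n_c = int(round(fraction / (1 - fraction) * len(primary_reads)))
    if n_c > len(contaminant_reads):
        raise ValueError(
            f"contaminant pool too small: need {n_c}, have {len(contaminant_reads)}"
        )
    picked = rng.choice(len(contaminant_reads), size=n_c, replace=False)
    contams = [
        replace(
            contaminant_reads[j],
            read_id=f"co_{contaminant_reads[j].read_id}",
            is_carryover=True,
        )
        for j in picked
    ]
    merged = list(primary_reads) + contams
    order = rng.permutation(len(merged))
    return [merged[j] for j in order]
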