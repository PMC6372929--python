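"""Per-read species assignment and community profiles.

After chimera scrubbing, a read's hits are filtered by alignment block
length (>= 1,000 columns for 16S, >= 3,000 for the rrn amplicon) and the
hits with the highest AS score decide the call: one species -> ``assigned``;
a cross-species tie -> genus-level LCA call when the genera agree
(``ambiguous`` status with the genus recorded), else ``ambiguous`` with no
taxon.  Reads with hits but none passing the block filter are
``filtered_block``; reads with no hits are ``unassigned``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignmentHit
from .markers import get_marker
from .refdb import ReferenceDB

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"
FILTERED_BLOCK = "filtered_block"
CHIMERIC = "chimeric"
UNCOVERED = "uncovered"

STATUSES = (ASSIGNED, AMBIGUOUS, UNASSIGNED, FILTERED_BLOCK, CHIMERIC, UNCOVERED)


@dataclass(frozen=True)
class ClassifyParams:
    tie_policy: str = "ambiguous_to_lca"  # or "drop_ambiguous"
    min_block_override: int | None = None

    def min_block(self, marker) -> int:
        if self.min_block_override is not None:
            if self.min_block_override <= 0:
                raise ValueError("min_block must be > 0")
            return self.min_block_override
        return get_marker(marker).min_block


@dataclass(frozen=True)
class TaxonomicAssignment:
    read_id: str
    status: str
    species: str = ""
    genus: str = ""
    as_score: int = 0
    n_best_ties: int = 0


def filter_hits(
    hits: list[AlignmentHit], marker, params: ClassifyParams = ClassifyParams()
) -> list[AlignmentHit]:
    """Keep hits whose alignment block is >= the marker's threshold."""
    mb = params.min_block(marker)
    return [h for h in hits if h.block_length >= mb]


def assign_read(
    hits: list[AlignmentHit],
    db: ReferenceDB,
    params: ClassifyParams = ClassifyParams(),
) -> TaxonomicAssignment:
    """Assign one read from its block-filtered hits by the best-AS rule."""
    if not hits:
        return TaxonomicAssignment(read_id="", status=UNASSIGNED)
    read_id = hits[0].read_id
    best = max(h.as_score for h in hits)
    winners = [h for h in hits if h.as_score == best]
    winners.sort(key=lambda h: (h.ref_id, h.ref_start))
    species = {db.get(h.ref_id).species for h in winners}
    if len(species) == 1:
        top = winners[0]
        rec = db.get(top.ref_id)
        return TaxonomicAssignment(
            read_id, ASSIGNED, rec.species, rec.genus, best, len(winners)
        )
    genera = {db.get(h.ref_id).genus for h in winners}
    if params.tie_policy == "ambiguous_to_lca" and len(genera) == 1:
        return TaxonomicAssignment(
            read_id, AMBIGUOUS, "", genera.pop(), best, len(winners)
        )
    return TaxonomicAssignment(read_id, AMBIGUOUS, "", "", best, len(winners))


def assign_reads(
    hits_by_read: dict[str, list[AlignmentHit]],
    db: ReferenceDB,
    marker,
    params: ClassifyParams = ClassifyParams(),
    flags: dict[str, str] | None = None,
) -> list[TaxonomicAssignment]:
    """Assign every read, honouring chimera/uncovered flags when given."""
    flags = flags or {}
    out = []
    for read_id, hits in hits_by_read.items():
        flag = flags.get(read_id)
        if flag in (CHIMERIC, UNCOVERED):
            out.append(TaxonomicAssignment(read_id, flag))
            continue
        if not hits:
            out.append(TaxonomicAssignment(read_id, UNASSIGNED))
            continue
        kept = filter_hits(hits, marker, params)
        if not kept:
            out.append(TaxonomicAssignment(read_id, FILTERED_BLOCK))
            continue
        a = assign_read(kept, db, params)
        out.append(a)
    return out


@dataclass
class AbundanceTable:
    rank: str  # "species" | "genus"
    rows: pd.DataFrame  # columns: taxon, read_count, relative_abundance
    total_classified: int

    def count(self, taxon: str) -> int:
        m = self.rows[self.rows["taxon"] == taxon]
        return 0 if m.empty else int(m["read_count"].iloc[0])

    def abundance(self, taxon: str) -> float:
        m = self.rows[self.rows["taxon"] == taxon]
        return 0.0 if m.empty else float(m["relative_abundance"].iloc[0])

    @property
    def taxa(self) -> set[str]:
        return set(self.rows["taxon"])


def abundance_table(assignments: list[TaxonomicAssignment], rank: str = "species") -> AbundanceTable:
    """Read counts and relative abundances over the classified reads.

    At species rank only ``assigned`` reads count; at genus rank genus-level
    LCA calls (ambiguous with an agreed genus) count too.  Relative
    abundances are over classified reads, not all sequenced reads.
    """
    if rank not in ("species", "genus"):
        raise ValueError(f"unknown rank {rank!r}")
    counts: dict[str, int] = {}
    for a in assignments:
        if rank == "species":
            if a.status == ASSIGNED:
                counts[a.species] = counts.get(a.species, 0) + 1
        else:
            if a.genus:
                counts[a.genus] = counts.get(a.genus, 0) + 1
    total = sum(counts.values())
    rows = pd.DataFrame(
        {
            "taxon": list(counts.keys()),
            "read_count": list(counts.values()),
        }
    ).sort_values("read_count", ascending=False, kind="stable", ignore_index=True)
    if total:
        rows["relative_abundance"] = rows["read_count"] / total
    else:
        rows["relative_abundance"] = pd.Series(dtype=float)
    return AbundanceTable(rank, rows, total)


def assignments_frame(assignments: list[TaxonomicAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [a.read_id for a in assignments],
            "status": [a.status for a in assignments],
            "species": [a.species for a in assignments],
            "genus": [a.genus for a in assignments],
            "as_score": [a.as_score for a in assignments],
            "n_best_ties": [a.n_best_ties for a in assignments],
        }
    )


def rarefaction_curve(
    assignments: list[TaxonomicAssignment],
    depths: list[int],
    replicates: int = 10,
    seed: int = 0,
    rank: str = "species",
) -> pd.DataFrame:
    """Observed-taxa rarefaction over random subsamples without replacement.

    Depths exceeding the number of classified reads are skipped with a
    warning.  Deterministic given ``seed``.
    """
    import warnings

    if rank == "species":
        taxa = np.array([a.species for a in assignments if a.status == ASSIGNED])
    else:
        taxa = np.array([a.genus for a in assignments if a.genus])
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > len(taxa):
            warnings.warn(f"depth {depth} exceeds {len(taxa)} classified reads; skipped",
                          stacklevel=2)
            continue
        obs = [
            len(np.unique(rng.choice(taxa, size=depth, replace=False)))
            for _ in range(replicates)
        ]
        rows.append(
            {
                "depth": depth,
                "mean_observed_taxa": float(np.mean(obs)),
                "sd_observed_taxa": float(np.std(obs, ddof=1)) if replicates > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
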