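"""Reference marker database: taxonomically labelled 16S / rrn sequences.

A :class:`ReferenceDB` holds one :class:`ReferenceRecord` per reference
sequence (a species may contribute several operon copies) together with a
rank -> name -> ref_ids index used for taxon subsetting.  Headers follow a
configurable ``ref_id|rank=name;...;species=Genus species`` scheme; the
format of published operon databases varies, so the parser is a convention
of this package, not a claim about any particular upstream file.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO

from .markers import Marker, get_marker

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference marker sequence with its taxonomic lineage."""

    ref_id: str
    species: str
    genus: str
    lineage: tuple[tuple[str, str], ...]  # (rank, name) ordered domain -> species
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"{self.ref_id}: empty sequence")
        extra = set(seq) - _VALID_BASES
        if extra:
            raise ValueError(f"{self.ref_id}: invalid bases {sorted(extra)}")
        if not self.species or not self.genus:
            raise ValueError(f"{self.ref_id}: species and genus must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def rank_name(self, rank: str) -> str | None:
        for r, n in self.lineage:
            if r == rank:
                return n
        return None


@dataclass
class HeaderScheme:
    """Delimiter-based taxonomy parser for FASTA headers.

    Default scheme: ``refid|domain=Bacteria;...;genus=G;species=G s``.
    At minimum ``species`` and ``genus`` must be recoverable.
    """

    id_delimiter: str = "|"
    field_sep: str = ";"
    kv_sep: str = "="

    def parse(self, header: str) -> dict | None:
        """Parse a header into record fields (without the sequence), or None
        when no species can be recovered."""
        ref_id, _, rest = header.partition(self.id_delimiter)
        fields = {}
        for part in rest.split(self.field_sep):
            part = part.strip()
            if not part:
                continue
            key, sep, val = part.partition(self.kv_sep)
            if sep:
                fields[key.strip()] = val.strip()
        if not fields.get("species"):
            return None
        if "genus" not in fields:
            fields["genus"] = fields["species"].split()[0]
        lineage = tuple((r, fields[r]) for r in RANKS if r in fields)
        return {
            "ref_id": ref_id.strip(),
            "species": fields["species"],
            "genus": fields["genus"],
            "lineage": lineage,
        }

    def format(self, rec: ReferenceRecord) -> str:
        parts = [f"{r}{self.kv_sep}{n}" for r, n in rec.lineage]
        return f"{rec.ref_id}{self.id_delimiter}{self.field_sep.join(parts)}"


class ReferenceDB:
    """Indexed collection of reference records for one marker."""

    def __init__(self, records: list[ReferenceRecord], marker: "str | Marker"):
        self.marker: Marker = get_marker(marker)
        self.records: list[ReferenceRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.ref_id in seen:
                raise ValueError(f"duplicate ref_id: {rec.ref_id!r}")
            seen.add(rec.ref_id)
        self._by_id = {rec.ref_id: rec for rec in self.records}
        self.taxon_index: dict[str, dict[str, set[str]]] = {}
        for rec in self.records:
            for rank, name in rec.lineage:
                self.taxon_index.setdefault(rank, {}).setdefault(name, set()).add(
                    rec.ref_id
                )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id

    def get(self, ref_id: str) -> ReferenceRecord:
        return self._by_id[ref_id]

    @property
    def species(self) -> list[str]:
        """Distinct species names, in first-appearance order."""
        out, seen = [], set()
        for rec in self.records:
            if rec.species not in seen:
                seen.add(rec.species)
                out.append(rec.species)
        return out

    @property
    def n_species(self) -> int:
        return len(self.species)

    def refs_of_species(self, species: str) -> list[ReferenceRecord]:
        return [r for r in self.records if r.species == species]


def build_db(records: list[ReferenceRecord], marker: "str | Marker") -> ReferenceDB:
    return ReferenceDB(records, marker)


def load_reference_fasta(
    path, marker: "str | Marker", header_scheme: HeaderScheme | None = None
) -> ReferenceDB:
    """Load a taxonomy-labelled reference FASTA into a :class:`ReferenceDB`.

    Raises ``ValueError`` listing every header whose taxonomy cannot be
    parsed (at least ``species`` is required), and on duplicate ref_ids.
    """
    scheme = header_scheme or HeaderScheme()
    records: list[ReferenceRecord] = []
    bad_headers: list[str] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        parsed = scheme.parse(entry.description)
        if parsed is None:
            bad_headers.append(entry.description)
            continue
        records.append(ReferenceRecord(sequence=str(entry.seq), **parsed))
    if bad_headers:
        raise ValueError(
            "headers lacking a parseable species field: " + ", ".join(bad_headers)
        )
    return ReferenceDB(records, marker)


def write_reference_fasta(
    db: ReferenceDB, path, header_scheme: HeaderScheme | None = None, width: int = 80
) -> None:
    scheme = header_scheme or HeaderScheme()
    with open(path, "w") as fh:
        for rec in db.records:
            fh.write(f">{scheme.format(rec)}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def taxonomy_table(db: ReferenceDB):
    """Taxonomy export: one row per record, one column per rank."""
    import pandas as pd

    rows = []
    for rec in db.records:
        row = {"ref_id": rec.ref_id, "length": rec.length}
        row.update({rank: name for rank, name in rec.lineage})
        rows.append(row)
    return pd.DataFrame(rows)


def subset_excluding_taxon(db: ReferenceDB, rank: str, name: str) -> ReferenceDB:
    """Return a new DB without any record carrying (rank, name) in its lineage.

    Emulates removing a whole class (e.g. Gammaproteobacteria) from the
    reference database to probe incomplete-database behaviour.  An absent
    name is a no-op (logged); removing everything is allowed but warned.
    """
    present = db.taxon_index.get(rank, {}).get(name)
    if not present:
        logger.info("subset_excluding_taxon: %r not present at rank %r", name, rank)
        return ReferenceDB(db.records, db.marker)
    kept = [rec for rec in db.records if rec.rank_name(rank) != name]
    if not kept:
        warnings.warn(
            f"excluding {rank}={name} removed every record", stacklevel=2
        )
    return ReferenceDB(kept, db.marker)


def add_reference(db: ReferenceDB, record: ReferenceRecord) -> ReferenceDB:
    """Return a new DB with ``record`` appended (duplicate ref_id is an error)."""
    if record.ref_id in db:
        raise ValueError(f"duplicate ref_id: {record.ref_id!r}")
    return ReferenceDB(db.records + [record], db.marker)
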