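"""Lightweight FASTQ I/O shared by the pipeline stages.

Reads are passed between stages as simple records with ``read_id``,
``sequence`` and ``quality`` attributes; the simulator's SyntheticRead
satisfies the same protocol.  Parsing goes through Biopython; writing is
done directly so that identical inputs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO


@dataclass
class Read:
    read_id: str
    sequence: str
    quality: str = ""

    def __post_init__(self):
        if self.quality and len(self.quality) != len(self.sequence):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fastq(path) -> list[Read]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(Read(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
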