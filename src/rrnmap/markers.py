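"""Marker definitions for the two ribosomal amplicons.

The pipeline profiles communities with one of two markers: the full-length
16S rRNA gene (~1,500 bp) or the 16S-ITS-23S span of the rrn operon
(~4,300 bp).  Each marker carries the length-selection window applied after
end trimming and the minimum alignment block length required before a read
may be assigned to a species.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Marker:
    name: str
    nominal_length: int
    length_window: tuple[int, int]  # inclusive [min, max] read length in bp
    min_block: int  # minimum alignment block length (columns) for assignment


MARKER_16S = Marker("16S", 1500, (1200, 1800), 1000)
MARKER_RRN = Marker("16S-ITS-23S", 4300, (3500, 5000), 3000)

_ALIASES = {
    "16s": MARKER_16S,
    "16s-its-23s": MARKER_RRN,
    "rrn": MARKER_RRN,
}


def get_marker(name: "str | Marker") -> Marker:
    """Resolve a marker by name (accepts ``16S``, ``16S-ITS-23S`` or ``rrn``)."""
    if isinstance(name, Marker):
        return name
    try:
        return _ALIASES[name.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown marker {name!r}; expected one of: 16S, 16S-ITS-23S (alias rrn)"
        ) from None
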