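"""Fixed-end trimming and marker-specific length selection.

The sequencing construct carries ~45 bp of universal tag + primer at each
end; those are cut with a fixed trim.  After trimming, reads are selected by
size into the marker's window (inclusive on both bounds): 1,200-1,800 bp for
the full-length 16S gene, 3,500-5,000 bp for the 16S-ITS-23S amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .markers import Marker, get_marker


@dataclass(frozen=True)
class PreprocessParams:
    end_trim_bp: int = 45
    length_windows: dict | None = None  # marker name -> (min, max); None = marker default

    def __post_init__(self):
        if self.end_trim_bp < 0:
            raise ValueError("end_trim_bp must be >= 0")
        if self.length_windows:
            for lo, hi in self.length_windows.values():
                if lo >= hi:
                    raise ValueError("length window min must be < max")

    def window(self, marker) -> tuple[int, int]:
        marker = get_marker(marker)
        if self.length_windows and marker.name in self.length_windows:
            return tuple(self.length_windows[marker.name])
        return marker.length_window


def trim_fixed_ends(read, n: int):
    """Cut ``n`` bases off both ends; returns None when nothing remains."""
    if n < 0:
        raise ValueError("trim length must be >= 0")
    if n == 0:
        return read
    if len(read.sequence) <= 2 * n:
        return None
    return replace(
        read,
        sequence=read.sequence[n:-n],
        quality=read.quality[n:-n] if read.quality else read.quality,
    )


def trim_reads(reads, n: int):
    """Trim all reads; returns (kept, n_rejected)."""
    kept = []
    rejected = 0
    for r in reads:
        t = trim_fixed_ends(r, n)
        if t is None:
            rejected += 1
        else:
            kept.append(t)
    return kept, rejected


def filter_by_length(reads, marker, params: PreprocessParams = PreprocessParams()):
    """Keep reads inside the marker's inclusive length window.

    Returns (kept, stats) with stats counting input / kept /
    discarded_short / discarded_long.
    """
    lo, hi = params.window(marker)
    kept, short, long_ = [], 0, 0
    for r in reads:
        n = len(r.sequence)
        if n < lo:
            short += 1
        elif n > hi:
            long_ += 1
        else:
            kept.append(r)
    stats = {
        "input": len(reads),
        "kept": len(kept),
        "discarded_short": short,
        "discarded_long": long_,
    }
    return kept, stats


def preprocess_reads(reads, marker, params: PreprocessParams = PreprocessParams()):
    """Trim then length-select; returns (kept, stats)."""
    trimmed, rejected = trim_reads(reads, params.end_trim_bp)
    kept, stats = filter_by_length(trimmed, marker, params)
    stats = {"input": len(reads), "trim_rejected": rejected, **{k: v for k, v in stats.items() if k != "input"}}
    return kept, stats
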