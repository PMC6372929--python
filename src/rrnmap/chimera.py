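"""Chimera scrubbing from per-read alignment coverage.

A read's hits against the classification database are collapsed into a
coverage profile over read positions.  Reads are flagged:

* ``chimeric`` when an internal uncovered run of at least
  ``min_internal_gap`` bp lies strictly between two covered intervals, or
  when two hits from *different* references support essentially disjoint
  read intervals, each at least ``min_segment_bp`` long (split-alignment
  evidence).  The second rule carries most of the sensitivity against a
  complete database: the two parent alignments of a chimera abut at the
  junction, so the uncovered run between them is usually only a few bases.
* ``uncovered`` when the covered fraction of the read is below
  ``min_covered_fraction`` (typically reads whose species has no usable
  reference).
* ``clean`` otherwise; uncovered read *ends* are permitted.

Flagged reads are excluded from classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import AlignmentHit

CLEAN = "clean"
CHIMERIC = "chimeric"
UNCOVERED = "uncovered"


@dataclass(frozen=True)
class ChimeraParams:
    min_cov: int = 1
    min_internal_gap: int = 100
    min_covered_fraction: float = 0.8
    min_segment_bp: int = 400  # minimum length of each split-alignment segment
    max_segment_overlap: float = 0.2  # of the shorter segment


@dataclass
class CoverageProfile:
    read_id: str
    read_length: int
    covered_intervals: list[tuple[int, int]]
    # (ref_id, read_start, read_end) of the contributing hits, kept for the
    # split-alignment rule
    hit_spans: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def covered_fraction(self) -> float:
        return sum(e - s for s, e in self.covered_intervals) / self.read_length

    @property
    def largest_internal_gap(self) -> int:
        iv = self.covered_intervals
        if len(iv) < 2:
            return 0
        return max(iv[i + 1][0] - iv[i][1] for i in range(len(iv) - 1))


def compute_coverage(
    hits: list[AlignmentHit], read_length: int, min_cov: int = 1
) -> CoverageProfile:
    """Union of read intervals covered by >= min_cov hits of one read."""
    if hits:
        ids = {h.read_id for h in hits}
        if len(ids) > 1:
            raise ValueError(f"hits from multiple reads: {sorted(ids)}")
    events = []
    for h in hits:
        events.append((h.read_start, 1))
        events.append((h.read_end, -1))
    events.sort()
    intervals: list[tuple[int, int]] = []
    depth = 0
    start = None
    for pos, delta in events:
        before = depth
        depth += delta
        if before < min_cov <= depth:
            start = pos
        elif before >= min_cov > depth and start is not None:
            if pos > start:
                intervals.append((start, pos))
            start = None
    # merge touching intervals
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    read_id = hits[0].read_id if hits else ""
    spans = sorted((h.ref_id, h.read_start, h.read_end) for h in hits)
    return CoverageProfile(read_id, read_length, merged, spans)


def _split_evidence(profile: CoverageProfile, params: ChimeraParams) -> bool:
    spans = [
        (r, s, e)
        for r, s, e in profile.hit_spans
        if e - s >= params.min_segment_bp
    ]
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            r1, s1, e1 = spans[i]
            r2, s2, e2 = spans[j]
            if r1 == r2:
                continue
            ov = min(e1, e2) - max(s1, s2)
            shorter = min(e1 - s1, e2 - s2)
            if ov < params.max_segment_overlap * shorter:
                return True
    return False


def classify_profile(profile: CoverageProfile, params: ChimeraParams = ChimeraParams()) -> str:
    if not profile.covered_intervals:
        return UNCOVERED
    if profile.largest_internal_gap >= params.min_internal_gap:
        return CHIMERIC
    if _split_evidence(profile, params):
        return CHIMERIC
    if profile.covered_fraction < params.min_covered_fraction:
        return UNCOVERED
    return CLEAN


def detect_chimeras(
    profiles: list[CoverageProfile], params: ChimeraParams = ChimeraParams()
) -> dict[str, str]:
    """Flag each read clean / chimeric / uncovered from its coverage profile."""
    return {p.read_id: classify_profile(p, params) for p in profiles}


def flag_reads(
    hits_by_read: dict[str, list[AlignmentHit]],
    read_lengths: dict[str, int],
    params: ChimeraParams = ChimeraParams(),
) -> pd.DataFrame:
    """Coverage + flags for every read; returns the flags table
    (read_id, status, covered_fraction, largest_internal_gap)."""
    rows = []
    for read_id, hits in hits_by_read.items():
        profile = compute_coverage(hits, read_lengths[read_id], params.min_cov)
        profile.read_id = read_id
        status = classify_profile(profile, params)
        rows.append(
            {
                "read_id": read_id,
                "status": status,
                "covered_fraction": round(profile.covered_fraction, 4),
                "largest_internal_gap": profile.largest_internal_gap,
            }
        )
    return pd.DataFrame(rows)
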