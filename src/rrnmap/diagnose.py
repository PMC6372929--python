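"""Database-completeness diagnostics from best-hit score distributions.

When every community member has a reference, the per-read distributions of
alignment block length and AS score are left-skewed: one high mode near the
full amplicon.  When a major taxon is missing from the database its reads
are captured by short conserved-segment alignments, and both distributions
turn bimodal with a new low mode below the block threshold.  These
diagnostics histogram the winning hit per read, flag bimodality on a
smoothed histogram, and compare best hits between two databases read by
read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignmentHit


@dataclass
class ScoreHistogram:
    metric: str  # "block_length" | "as_score"
    bin_edges: np.ndarray
    counts: np.ndarray
    n_reads: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "count": self.counts,
            }
        )


@dataclass
class CompletenessReport:
    metric: str
    modes: list[tuple[float, float]]  # (location, mass fraction)
    is_bimodal: bool
    low_mode_mass_below_threshold: float


def best_hits_per_read(hits_by_read: dict[str, list[AlignmentHit]]) -> list[AlignmentHit]:
    """The winning (highest-AS) hit of every read that has at least one hit."""
    out = []
    for hits in hits_by_read.values():
        if hits:
            out.append(max(hits, key=lambda h: (h.as_score, h.ref_id <= h.ref_id)))
    return out


def score_distributions(
    hits: list[AlignmentHit], metric: str = "block_length", bins: int = 50
) -> ScoreHistogram:
    """Histogram of a per-read best-hit metric."""
    if metric not in ("block_length", "as_score"):
        raise ValueError(f"unknown metric {metric!r}")
    if not hits:
        raise ValueError("no hits to diagnose")
    values = np.array(
        [h.block_length if metric == "block_length" else h.as_score for h in hits],
        dtype=float,
    )
    counts, edges = np.histogram(values, bins=bins)
    return ScoreHistogram(metric, edges, counts, len(values))


def completeness_flag(
    hist: ScoreHistogram,
    block_threshold: float,
    prominence: float = 0.05,
    smooth_bins: int = 5,
) -> CompletenessReport:
    """Flag bimodality on a moving-average-smoothed histogram.

    ``is_bimodal`` is true when two modes each hold at least ``prominence``
    of the total mass and are separated by a valley no higher than half the
    smaller mode's peak.  ``low_mode_mass_below_threshold`` is the fraction
    of reads whose metric falls below ``block_threshold``.
    """
    from scipy.signal import find_peaks

    counts = hist.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("degenerate histogram")
    kernel = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(counts, kernel, mode="same")
    # pad so peaks at the histogram edges are found too
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peak_idx, _ = find_peaks(padded)
    peak_idx = peak_idx - 1
    centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2

    # split the histogram into basins at the minima between adjacent peaks
    modes: list[tuple[float, float, float, int]] = []  # (loc, mass, height, idx)
    if len(peak_idx):
        boundaries = [0]
        for a, b in zip(peak_idx[:-1], peak_idx[1:]):
            boundaries.append(a + 1 + int(np.argmin(smooth[a + 1 : b + 1])))
        boundaries.append(len(counts))
        for p, lo, hi in zip(peak_idx, boundaries[:-1], boundaries[1:]):
            mass = counts[lo:hi].sum() / total
            modes.append((float(centers[p]), float(mass), float(smooth[p]), int(p)))
    prominent = [m for m in modes if m[1] >= prominence]
    is_bimodal = False
    for i in range(len(prominent)):
        for j in range(i + 1, len(prominent)):
            a, b = prominent[i], prominent[j]
            lo, hi = sorted((a[3], b[3]))
            valley = smooth[lo : hi + 1].min()
            if valley <= 0.5 * min(a[2], b[2]):
                is_bimodal = True
    low_mass = counts[centers < block_threshold].sum() / total
    return CompletenessReport(
        metric=hist.metric,
        modes=[(loc, mass) for loc, mass, _, _ in modes],
        is_bimodal=is_bimodal,
        low_mode_mass_below_threshold=float(low_mass),
    )


def compare_dbs(
    hits_full: dict[str, list[AlignmentHit]],
    hits_subset: dict[str, list[AlignmentHit]],
    species_of_full=None,
    species_of_subset=None,
) -> pd.DataFrame:
    """Paired per-read comparison of best hits against two databases.

    ``species_of_*`` map ref_id -> species (e.g. ``db.get(r).species``); when
    given, the table carries a ``same_species`` column.  Reads present on only
    one side are reported with the missing side flagged (NaN scores).
    """
    full_best = {h.read_id: h for h in best_hits_per_read(hits_full)}
    sub_best = {h.read_id: h for h in best_hits_per_read(hits_subset)}
    all_reads = set(hits_full) | set(hits_subset)
    if not (set(hits_full) & set(hits_subset)):
        raise ValueError("read sets of the two mappings are disjoint")
    rows = []
    for read_id in sorted(all_reads):
        f = full_best.get(read_id)
        s = sub_best.get(read_id)
        row = {
            "read_id": read_id,
            "as_full": f.as_score if f else np.nan,
            "as_subset": s.as_score if s else np.nan,
            "ref_full": f.ref_id if f else "",
            "ref_subset": s.ref_id if s else "",
            "missing_in": "" if (f and s) else ("subset" if f else "full"),
        }
        if species_of_full and species_of_subset and f and s:
            row["same_species"] = species_of_full(f.ref_id) == species_of_subset(s.ref_id)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["delta_as"] = df["as_full"] - df["as_subset"]
    return df


def compare_summary(df: pd.DataFrame) -> dict:
    both = df[df["missing_in"] == ""]
    out = {
        "n_reads": int(len(df)),
        "n_paired": int(len(both)),
        "median_delta_as": float(both["delta_as"].median()) if len(both) else float("nan"),
        "median_as_full": float(both["as_full"].median()) if len(both) else float("nan"),
        "median_as_subset": float(both["as_subset"].median()) if len(both) else float("nan"),
    }
    if "same_species" in df.columns and len(both):
        out["species_concordance"] = float(both["same_species"].mean())
    return out
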