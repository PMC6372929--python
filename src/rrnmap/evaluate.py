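"""Scoring pipeline output against mock-community truth.

Covers the mock-community analyses: which expected species were detected,
how observed proportions track expected operon copies (log-log ordinary
least squares), per-read assignment accuracy at species and genus rank
(unconditional over all evaluable reads and conditional on assignment), and
the share of composition attributable to carryover contamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    AMBIGUOUS,
    ASSIGNED,
    FILTERED_BLOCK,
    UNASSIGNED,
    AbundanceTable,
    TaxonomicAssignment,
)


@dataclass
class MockTruth:
    """Expected community composition: species -> copies or proportions."""

    members: list[tuple[str, float]]
    value_kind: str = "operon_copies"  # or "proportion_16S_content"

    def __post_init__(self):
        if any(v <= 0 for _, v in self.members):
            raise ValueError("expected values must be > 0")
        names = [s for s, _ in self.members]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species in truth")

    @property
    def species(self) -> list[str]:
        return [s for s, _ in self.members]

    @classmethod
    def from_design(cls, design) -> "MockTruth":
        kind = (
            "operon_copies"
            if design.weight_kind == "operon_copies"
            else "proportion_16S_content"
        )
        return cls(list(design.members), kind)


def detection_report(
    table: AbundanceTable, truth: MockTruth, min_reads: int = 1
) -> tuple[list[str], list[str], list[str]]:
    """(detected, missed, false_positives) at a read-count threshold."""
    detected, missed = [], []
    for sp in truth.species:
        (detected if table.count(sp) >= min_reads else missed).append(sp)
    false_pos = sorted(t for t in table.taxa if t not in set(truth.species))
    return detected, missed, false_pos


def abundance_regression(table: AbundanceTable, truth: MockTruth):
    """OLS of log10(observed proportion) on log10(expected value).

    Zero-count species are excluded (and reported); at least three usable
    points are required.  Returns (slope, intercept, r_squared, excluded).
    """
    xs, ys, excluded = [], [], []
    for sp, expect in truth.members:
        obs = table.abundance(sp)
        if obs <= 0:
            excluded.append(sp)
            continue
        xs.append(np.log10(expect))
        ys.append(np.log10(obs))
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} species with nonzero observed proportion")
    res = stats.linregress(xs, ys)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), excluded


def read_accuracy(
    assignments: list[TaxonomicAssignment], truth: pd.DataFrame
) -> dict:
    """Per-rank assignment accuracy against the simulator truth table.

    Evaluable reads are the non-chimeric, non-carryover truth reads that
    reached classification (status assigned / ambiguous / unassigned /
    filtered_block).  Unconditional accuracy divides correct assignments by
    all evaluable reads; conditional accuracy divides by assigned reads only.
    """
    t = truth.set_index("read_id")
    genus_of = {}  # truth genus = first token of the species name
    for a in assignments:
        if a.read_id not in t.index:
            raise ValueError(f"read {a.read_id!r} missing from truth table")
    out = {}
    eval_statuses = {ASSIGNED, AMBIGUOUS, UNASSIGNED, FILTERED_BLOCK}
    rows = [
        (a, t.loc[a.read_id])
        for a in assignments
        if not t.loc[a.read_id, "is_chimera"] and not t.loc[a.read_id, "is_carryover"]
    ]
    evaluable = [(a, tr) for a, tr in rows if a.status in eval_statuses]
    n_eval = len(evaluable)
    n_assigned = sum(1 for a, _ in evaluable if a.status == ASSIGNED)
    correct_sp = sum(
        1 for a, tr in evaluable if a.status == ASSIGNED and a.species == tr["truth_species"]
    )
    def truth_genus(tr):
        return tr["truth_species"].split()[0]
    with_genus = [(a, tr) for a, tr in evaluable if a.genus]
    correct_gen = sum(1 for a, tr in with_genus if a.genus == truth_genus(tr))
    out["n_evaluable"] = n_eval
    out["n_assigned"] = n_assigned
    out["species"] = {
        "unconditional": correct_sp / n_eval if n_eval else float("nan"),
        "conditional": correct_sp / n_assigned if n_assigned else float("nan"),
    }
    out["genus"] = {
        "unconditional": correct_gen / n_eval if n_eval else float("nan"),
        "conditional": correct_gen / len(with_genus) if with_genus else float("nan"),
    }
    return out


def carryover_estimate(
    table: AbundanceTable,
    contaminant_taxa: set[str],
    sample_taxa: set[str] | None = None,
) -> tuple[float, list[str]]:
    """Share of composition from contaminant-only taxa.

    Taxa appearing in both the contaminant set and the expected sample are
    excluded from the estimate and returned for reporting (they cannot be
    attributed to carryover from composition alone).
    """
    overlapping = sorted(contaminant_taxa & sample_taxa) if sample_taxa else []
    usable = contaminant_taxa - set(overlapping)
    if not usable and overlapping:
        import warnings

        warnings.warn(
            "all contaminant taxa overlap the expected sample; estimate is 0 "
            f"(excluded: {overlapping})",
            stacklevel=2,
        )
    est = float(sum(table.abundance(t) for t in usable))
    return est, overlapping


def evaluation_report(
    table: AbundanceTable,
    truth_design: MockTruth,
    assignments: list[TaxonomicAssignment] | None = None,
    truth_reads: pd.DataFrame | None = None,
    min_reads: int = 1,
) -> dict:
    """Bundle detection, regression and (when truth reads are given) accuracy."""
    detected, missed, false_pos = detection_report(table, truth_design, min_reads)
    report = {
        "detected": detected,
        "missed": missed,
        "false_positives": false_pos,
        "n_detected": len(detected),
    }
    try:
        slope, intercept, r2, excluded = abundance_regression(table, truth_design)
        report["regression"] = {
            "slope": slope,
            "intercept": intercept,
            "r_squared": r2,
            "excluded": excluded,
        }
    except ValueError as exc:
        report["regression"] = {"error": str(exc)}
    if assignments is not None and truth_reads is not None:
        report["accuracy"] = read_accuracy(assignments, truth_reads)
    return report
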