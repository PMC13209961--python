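"""Candidate triage against soft/hard docking-score thresholds.

The decision rule, applied per docking record:

1. a record must meet at least two of the three *soft* thresholds
   (affinity ≤ soft, pose score ≥ soft, CNN affinity ≥ soft — inclusive);
2. every metric that misses its soft threshold must still satisfy its
   *hard* bound (the benchmark extreme); any hard violation rejects the
   record regardless of the other metrics.

Interaction inspection (hinge/DFG contacts and the like) is deliberately
not automated; a free-text ``interaction_note`` rides along for curators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .benchmark_stats import ThresholdSet
from .chem_io import DockingRecord, ScoreTable

_METRIC_NAMES = ("affinity", "pose", "cnn_affinity")


@dataclass
class TriageDecision:
    record: DockingRecord
    soft_passes: frozenset[str]
    hard_violations: frozenset[str]
    accepted: bool
    rationale: str
    interaction_note: Optional[str] = None


@dataclass
class TriageReport:
    decisions: list[TriageDecision]
    n_accepted: int

    @property
    def n_rejected(self) -> int:
        return len(self.decisions) - self.n_accepted

    def accepted_ids(self) -> list[str]:
        return [d.record.ligand_id for d in self.decisions if d.accepted]


def evaluate(record: DockingRecord, thresholds: ThresholdSet) -> TriageDecision:
    """Apply the two-of-three-soft / no-hard-violation rule to one record.

    All comparisons are inclusive and use unrounded values.  A category
    override registered for the record's target replaces the affinity soft
    threshold at evaluation time.
    """
    aff_soft = thresholds.affinity_soft_for(record.target_id)
    soft = {
        "affinity": record.affinity <= aff_soft,
        "pose": record.cnn_pose_score >= thresholds.pose_soft,
        "cnn_affinity": record.cnn_affinity >= thresholds.cnn_affinity_soft,
    }
    hard_ok = {
        "affinity": record.affinity <= thresholds.affinity_hard,
        "pose": record.cnn_pose_score >= thresholds.pose_hard,
        "cnn_affinity": record.cnn_affinity >= thresholds.cnn_affinity_hard,
    }
    soft_passes = frozenset(m for m in _METRIC_NAMES if soft[m])
    hard_violations = frozenset(m for m in _METRIC_NAMES if not soft[m] and not hard_ok[m])
    accepted = len(soft_passes) >= 2 and not hard_violations
    parts = [f"soft passes: {', '.join(sorted(soft_passes)) or 'none'}"]
    if hard_violations:
        parts.append(f"hard violations: {', '.join(sorted(hard_violations))}")
    if record.target_id in thresholds.category_overrides:
        parts.append(f"affinity soft threshold overridden to {aff_soft:.2f} for {record.target_id}")
    parts.append("accepted" if accepted else "rejected")
    return TriageDecision(
        record=record,
        soft_passes=soft_passes,
        hard_violations=hard_violations,
        accepted=accepted,
        rationale="; ".join(parts),
    )


def triage_table(candidates: ScoreTable, thresholds: ThresholdSet) -> TriageReport:
    """Evaluate every record, preserving input order; count acceptances."""
    decisions = [evaluate(r, thresholds) for r in candidates.records]
    return TriageReport(decisions=decisions, n_accepted=sum(d.accepted for d in decisions))


def decisions_frame(report: TriageReport):
    """Decisions as a DataFrame for CSV export."""
    import pandas as pd

    rows = []
    for d in report.decisions:
        rows.append(
            {
                "ligand_id": d.record.ligand_id,
                "target_id": d.record.target_id,
                "accepted": d.accepted,
                "soft_passes": "|".join(sorted(d.soft_passes)),
                "hard_violations": "|".join(sorted(d.hard_violations)),
                "rationale": d.rationale,
                "interaction_note": d.interaction_note or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ligand_id",
            "target_id",
            "accepted",
            "soft_passes",
            "hard_violations",
            "rationale",
            "interaction_note",
        ],
    )
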