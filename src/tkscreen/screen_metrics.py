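"""Docking-protocol validation metrics.

* **Pose RMSD** between a reference (co-crystal) ligand geometry and a
  docked pose, minimized over the automorphisms of the element-colored
  heavy-atom bond graph so that chemically equivalent atoms (a flipped
  phenyl ring, a swapped carboxylate) never inflate the error.  IN_PLACE
  mode keeps both poses in the receptor frame — the re-/cross-docking
  convention; SUPERPOSED mode additionally removes the best rigid motion
  (Kabsch least squares with a reflection guard).  Quality bands:
  < 2.0 Å consistent, 2.0–3.0 Å deviated, > 3.0 Å inaccurate.

* **Enrichment factor** EF(x%) = (actives_x / dataset_x) /
  (actives_total / dataset_total) over the top x% of a ranked screen,
  with dataset_x = floor(x·N/100).

* **ROC-AUC** as the probability that a random active outranks a random
  inactive (ties half-credit), with the full threshold-sweep curve.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism
from scipy.spatial.transform import Rotation
from sklearn.metrics import roc_auc_score, roc_curve

from .chem_io import CompoundRecord

AUTOMORPHISM_CAP = 10_000


class RmsdMode(enum.Enum):
    IN_PLACE = "in_place"
    SUPERPOSED = "superposed"


class PoseQuality(enum.Enum):
    CONSISTENT = "consistent"  # < 2.0 Å
    DEVIATED = "deviated"  # 2.0–3.0 Å
    INACCURATE = "inaccurate"  # > 3.0 Å


@dataclass
class PoseComparison:
    rmsd: float
    n_atoms: int
    mapping: tuple[int, ...]  # pose atom index for each ref atom index
    mode: RmsdMode
    quality: PoseQuality
    automorphisms_searched: int = 1
    capped: bool = False


@dataclass(frozen=True)
class EnrichmentInput:
    x_pct: float
    dataset_total: int
    actives_total: int
    dataset_x: int
    actives_x: int


@dataclass(frozen=True)
class EnrichmentResult:
    ef: float
    input: EnrichmentInput
    ranking_metric: str = ""

    @property
    def ef_max(self) -> float:
        return self.input.dataset_total / self.input.actives_total


@dataclass
class RocResult:
    auc: float
    curve: list[tuple[float, float]]  # (FPR, TPR)


def classify_rmsd(rmsd: float) -> PoseQuality:
    """Band an RMSD value: < 2 Å consistent, 2–3 Å deviated, > 3 Å inaccurate."""
    if rmsd < 0 or not math.isfinite(rmsd):
        raise ValueError(f"RMSD must be finite and non-negative, got {rmsd}")
    if rmsd < 2.0:
        return PoseQuality.CONSISTENT
    if rmsd <= 3.0:
        return PoseQuality.DEVIATED
    return PoseQuality.INACCURATE


def _bond_graph(record: CompoundRecord) -> nx.Graph:
    if record.conformer is None:
        raise ValueError(f"record {record.id!r} has no conformer")
    g = nx.Graph()
    for idx, (sym, *_xyz) in enumerate(record.conformer):
        g.add_node(idx, element=sym)
    for i, j, _order in record.bonds or []:
        g.add_edge(i, j)
    return g


def _kabsch_rmsd(ref: np.ndarray, pose: np.ndarray) -> float:
    """Least-squares RMSD after optimal proper rotation + translation."""
    ref_c = ref - ref.mean(axis=0)
    pose_c = pose - pose.mean(axis=0)
    # align_vectors returns a proper rotation (reflections excluded by design)
    rot, _rssd = Rotation.align_vectors(ref_c, pose_c)
    diff = ref_c - rot.apply(pose_c)
    return float(np.sqrt((diff**2).sum() / len(ref)))


def pose_rmsd(
    ref: CompoundRecord, pose: CompoundRecord, mode: RmsdMode = RmsdMode.IN_PLACE
) -> PoseComparison:
    """Symmetry-aware heavy-atom RMSD between two conformers of one molecule.

    Both records must share the same element-colored bond topology.  The
    RMSD is minimized over graph automorphisms (capped at
    ``AUTOMORPHISM_CAP``; beyond the cap only the mappings enumerated so
    far plus the identity-style canonical mapping are considered and the
    result is flagged ``capped``).
    """
    g_ref, g_pose = _bond_graph(ref), _bond_graph(pose)
    matcher = isomorphism.GraphMatcher(
        g_ref, g_pose, node_match=isomorphism.categorical_node_match("element", None)
    )
    if not matcher.is_isomorphic():
        raise ValueError(
            f"molecular graphs of {ref.id!r} and {pose.id!r} do not match "
            "(element multiset or bond topology differ)"
        )
    xyz_ref, xyz_pose = ref.coords(), pose.coords()
    n = len(xyz_ref)
    if mode is RmsdMode.SUPERPOSED and n < 3:
        raise ValueError("superposed RMSD needs at least 3 atoms")

    best_rmsd = math.inf
    best_mapping: Optional[tuple[int, ...]] = None
    searched = 0
    capped = False
    for iso in matcher.isomorphisms_iter():
        searched += 1
        if searched > AUTOMORPHISM_CAP:
            capped = True
            break
        perm = tuple(iso[i] for i in range(n))
        p = xyz_pose[list(perm)]
        if mode is RmsdMode.IN_PLACE:
            rmsd = float(np.sqrt(((xyz_ref - p) ** 2).sum() / n))
        else:
            rmsd = _kabsch_rmsd(xyz_ref, p)
        if rmsd < best_rmsd:
            best_rmsd = rmsd
            best_mapping = perm
    assert best_mapping is not None
    return PoseComparison(
        rmsd=best_rmsd,
        n_atoms=n,
        mapping=best_mapping,
        mode=mode,
        quality=classify_rmsd(best_rmsd),
        automorphisms_searched=min(searched, AUTOMORPHISM_CAP),
        capped=capped,
    )


def _ranked(
    scores: Sequence[tuple[str, float, bool]], higher_is_better: bool
) -> list[tuple[str, float, bool]]:
    sign = -1.0 if higher_is_better else 1.0
    return sorted(scores, key=lambda t: (sign * t[1], t[0]))  # stable id tie-break


def enrichment_factor(
    scores: Sequence[tuple[str, float, bool]],
    x_pct: float = 5.0,
    higher_is_better: bool = True,
    ranking_metric: str = "",
) -> EnrichmentResult:
    """Enrichment factor over the top x% of the ranked (id, score, active) list."""
    if not 0.0 < x_pct <= 100.0:
        raise ValueError(f"x_pct {x_pct} outside (0, 100]")
    n_total = len(scores)
    actives_total = sum(1 for _i, _s, a in scores if a)
    if actives_total == 0:
        raise ValueError("no active compounds in the score list")
    if actives_total == n_total:
        raise ValueError("no inactive compounds in the score list")
    dataset_x = math.floor(x_pct * n_total / 100.0)
    if dataset_x == 0:
        raise ValueError(f"top {x_pct}% of {n_total} compounds is empty")
    top = _ranked(scores, higher_is_better)[:dataset_x]
    actives_x = sum(1 for _i, _s, a in top if a)
    ef = (actives_x / dataset_x) / (actives_total / n_total)
    return EnrichmentResult(
        ef=ef,
        input=EnrichmentInput(
            x_pct=x_pct,
            dataset_total=n_total,
            actives_total=actives_total,
            dataset_x=dataset_x,
            actives_x=actives_x,
        ),
        ranking_metric=ranking_metric,
    )


def enrichment_from_counts(
    actives_x: int, dataset_x: int, actives_total: int, dataset_total: int, x_pct: float = 5.0
) -> EnrichmentResult:
    """EF from already-tallied counts (for published screens reported as counts)."""
    if actives_x > min(dataset_x, actives_total) or dataset_x > dataset_total:
        raise ValueError("inconsistent enrichment counts")
    if actives_total == 0 or dataset_x == 0:
        raise ValueError("zero actives or empty top fraction")
    ef = (actives_x / dataset_x) / (actives_total / dataset_total)
    return EnrichmentResult(
        ef=ef,
        input=EnrichmentInput(x_pct, dataset_total, actives_total, dataset_x, actives_x),
    )


def roc_auc(
    scores: Sequence[tuple[str, float, bool]], higher_is_better: bool = True
) -> RocResult:
    """ROC-AUC (rank statistic, ties half-credit) with the threshold-sweep curve."""
    labels = np.array([bool(a) for _i, _s, a in scores])
    values = np.array([s for _i, s, _a in scores], dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both active and inactive compounds")
    if not higher_is_better:
        values = -values
    auc = float(roc_auc_score(labels, values))
    fpr, tpr, _thr = roc_curve(labels, values)
    return RocResult(auc=auc, curve=list(zip(fpr.tolist(), tpr.tolist())))
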