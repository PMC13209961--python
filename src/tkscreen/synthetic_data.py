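"""Seeded generators for every input the pipeline consumes.

These emulate the statistical structure of the real inputs — per-target
docking-score distributions for benchmark work, labeled active/decoy score
sets with a controlled separation for enrichment/ROC work, Gaussian-jittered
conformers for RMSD work, and small template-derived compound libraries for
similarity and pharmacophore work — without requiring a docking engine or
database downloads.  Every generator is a pure function of its spec + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem_io import CompoundRecord, DockingRecord, ScoreTable
from .datasets import load_fda_benchmark


@dataclass(frozen=True)
class TargetSpec:
    target_id: str
    n_drugs: int
    mean_affinity: float
    sd_affinity: float
    mean_pose: float
    sd_pose: float
    mean_cnn_affinity: float
    sd_cnn_affinity: float

    def __post_init__(self) -> None:
        if self.n_drugs < 1:
            raise ValueError("n_drugs must be >= 1")
        if min(self.sd_affinity, self.sd_pose, self.sd_cnn_affinity) < 0:
            raise ValueError("SDs must be non-negative")


@dataclass(frozen=True)
class BenchmarkSpec:
    targets: tuple[TargetSpec, ...]
    seed: int = 0


@dataclass(frozen=True)
class ScreenSpec:
    """Active/decoy score sets: decoys ~ N(μ, σ), actives ~ N(μ + d·σ, σ)."""

    n_actives: int
    n_decoys: int
    shift_d: float = 1.0
    base_mean: float = 0.0
    base_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_actives < 1 or self.n_decoys < 1:
            raise ValueError("need at least one active and one decoy")
        if self.base_sd <= 0:
            raise ValueError("base_sd must be positive")


def default_benchmark_spec(seed: int = 0, scale: int = 1) -> BenchmarkSpec:
    """Benchmark spec whose per-target means and SDs are estimated from the
    shipped FDA-drug reference table; ``scale`` multiplies every group size.
    Illustrative of that table's structure, not ground truth."""
    frame = load_fda_benchmark().to_frame()
    targets = []
    for target, grp in frame.groupby("target_id", sort=False):
        targets.append(
            TargetSpec(
                target_id=str(target),
                n_drugs=len(grp) * scale,
                mean_affinity=float(grp["affinity"].mean()),
                sd_affinity=float(grp["affinity"].std(ddof=0)),
                mean_pose=float(grp["cnn_pose_score"].mean()),
                sd_pose=float(grp["cnn_pose_score"].std(ddof=0)),
                mean_cnn_affinity=float(grp["cnn_affinity"].mean()),
                sd_cnn_affinity=float(grp["cnn_affinity"].std(ddof=0)),
            )
        )
    return BenchmarkSpec(targets=tuple(targets), seed=seed)


def gen_benchmark(spec: BenchmarkSpec) -> ScoreTable:
    """Per-target normal draws; pose scores truncated (clipped) to [0, 1],
    CNN affinities floored just above zero."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for t in spec.targets:
        aff = rng.normal(t.mean_affinity, t.sd_affinity, t.n_drugs)
        pose = np.clip(rng.normal(t.mean_pose, t.sd_pose, t.n_drugs), 0.0, 1.0)
        cnn = np.maximum(rng.normal(t.mean_cnn_affinity, t.sd_cnn_affinity, t.n_drugs), 1e-6)
        for k in range(t.n_drugs):
            records.append(
                DockingRecord(
                    ligand_id=f"{t.target_id}-drug-{k:04d}",
                    target_id=t.target_id,
                    affinity=float(aff[k]),
                    cnn_pose_score=float(pose[k]),
                    cnn_affinity=float(cnn[k]),
                )
            )
    return ScoreTable(records, provenance=f"gen_benchmark(seed={spec.seed})")


def gen_screen_set(spec: ScreenSpec) -> list[tuple[str, float, bool]]:
    """Labeled (id, score, active) sequence with binormal separation d·σ."""
    rng = np.random.default_rng(spec.seed)
    actives = rng.normal(spec.base_mean + spec.shift_d * spec.base_sd, spec.base_sd, spec.n_actives)
    decoys = rng.normal(spec.base_mean, spec.base_sd, spec.n_decoys)
    out = [(f"active-{i:05d}", float(s), True) for i, s in enumerate(actives)]
    out += [(f"decoy-{i:05d}", float(s), False) for i, s in enumerate(decoys)]
    return out


def gen_perturbed_pose(
    ref_conformer: Sequence[tuple[str, float, float, float]], sigma: float, seed: int = 0
) -> list[tuple[str, float, float, float]]:
    """I.i.d. Gaussian displacement of each coordinate by N(0, sigma²)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, (len(ref_conformer), 3))
    return [
        (sym, x + float(dx), y + float(dy), z + float(dz))
        for (sym, x, y, z), (dx, dy, dz) in zip(ref_conformer, noise)
    ]


# template grammar for toy libraries: diaryl ureas, aryl amides and
# quinazolines — the scaffold families of ATP-competitive kinase inhibitors
_SCAFFOLDS = (
    "O=C(Nc1ccc({r1})cc1)Nc1ccc({r2})cc1",
    "O=C(Nc1ccc({r1})cc1)c1ccc({r2})cc1",
    "{r1}c1ccc2ncnc(Nc3ccc({r2})cc3)c2c1",
    "O=C(N{r3}c1ccc({r1})cc1)Nc1ccc({r2})cn1",
)
_SUBSTITUENTS = ("F", "Cl", "OC", "C", "N(C)C", "C(F)(F)F", "OCC", "[H]")
_METHYL_OR_H = ("", "(C)")


def gen_toy_library(n: int, seed: int = 0) -> list[CompoundRecord]:
    """Small random library drawn from the template grammar; every SMILES is
    guaranteed valid and canonical, ids are unique, duplicates allowed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        while True:
            scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
            smiles = scaffold.format(
                r1=_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))],
                r2=_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))],
                r3=_METHYL_OR_H[rng.integers(len(_METHYL_OR_H))],
            )
            mol = Chem.MolFromSmiles(smiles)
            if mol is not None:
                break
        records.append(CompoundRecord(id=f"cmpd-{i:04d}", smiles=Chem.MolToSmiles(mol)))
    return records
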