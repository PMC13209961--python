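"""Lightweight pharmacophore modeling and screening.

A pharmacophore model is a set of typed tolerance spheres — hydrogen-bond
acceptors (HAC) and donors (HDO), aromatic-ring centroids (ARO),
hydrophobic-fragment centroids (HPB), and formal charges (POS/NEG) — each
with a center in Å and a radius (defaults: HAC/HDO 0.5 Å, HPB 1.0 Å,
ARO 1.1 Å).  A ligand matches when a kind-compatible correspondence exists
that places every matched ligand feature inside its model sphere, after an
optional least-squares rigid alignment; hits are ranked by the residual
feature RMSD.

The module also carries the drug-likeness property windows used to
pre-filter screening libraries (ranges spanned by approved kinase
inhibitors) and an exclusion-sphere steric filter against receptor atoms.

Feature perception is SMARTS-driven from a versioned pattern file shipped
with the package; perception is deterministic so screening runs are
reproducible, but it is intentionally simpler than the perception logic of
commercial modeling suites.
"""

from __future__ import annotations

import enum
import itertools
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from scipy.spatial.transform import Rotation

from .chem_io import ChemIOError, CompoundRecord

ASSIGNMENT_CAP = 100_000


class FeatureKind(enum.Enum):
    HAC = "HAC"  # hydrogen-bond acceptor
    HDO = "HDO"  # hydrogen-bond donor
    ARO = "ARO"  # aromatic ring centroid
    HPB = "HPB"  # hydrophobic fragment centroid
    POS = "POS"  # formal positive charge
    NEG = "NEG"  # formal negative charge


DEFAULT_RADII = {
    FeatureKind.HAC: 0.5,
    FeatureKind.HDO: 0.5,
    FeatureKind.ARO: 1.1,
    FeatureKind.HPB: 1.0,
    FeatureKind.POS: 0.5,
    FeatureKind.NEG: 0.5,
}


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: FeatureKind
    center: tuple[float, float, float]
    radius: float = 0.0

    def __post_init__(self) -> None:
        r = self.radius if self.radius > 0 else DEFAULT_RADII[self.kind]
        object.__setattr__(self, "radius", r)
        if not all(math.isfinite(c) for c in self.center):
            raise ValueError("feature center must be finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass
class PharmacophoreModel:
    name: str
    features: list[PharmacophoreFeature]
    required_count: Optional[int] = None  # default: all features must match

    def __post_init__(self) -> None:
        if len(self.features) < 2:
            raise ValueError("a pharmacophore model needs at least 2 features")
        if self.required_count is None:
            self.required_count = len(self.features)
        if not 2 <= self.required_count <= len(self.features):
            raise ValueError("required_count must be between 2 and the feature count")

    def kind_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.kind.value] = out.get(f.kind.value, 0) + 1
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "name": self.name,
            "features": [
                {"kind": f.kind.value, "center": list(f.center), "radius": f.radius}
                for f in self.features
            ],
            "required_count": self.required_count,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PharmacophoreModel":
        p = Path(str(source))
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            name=d["name"],
            features=[
                PharmacophoreFeature(
                    kind=FeatureKind(f["kind"]),
                    center=tuple(f["center"]),
                    radius=f.get("radius", 0.0),
                )
                for f in d["features"]
            ],
            required_count=d.get("required_count"),
        )


@dataclass
class MatchResult:
    ligand_id: str
    correspondence: dict[int, int]  # model feature index -> ligand feature index
    feature_rmsd: float
    rotation: Optional[np.ndarray] = None  # 3x3, applied to the centered ligand
    translation: Optional[np.ndarray] = None
    inconclusive: bool = False  # assignment cap hit before an accepting match


@dataclass(frozen=True)
class PropertyWindow:
    """Inclusive drug-likeness windows (defaults: ranges of approved TKIs)."""

    mw: tuple[float, float] = (416.81, 461.47)  # Da
    tpsa: tuple[float, float] = (83.48, 95.83)  # Å²
    logp: tuple[float, float] = (2.62, 3.49)  # Crippen logP(o/w)
    n_rotatable: tuple[int, int] = (5, 7)
    n_hba: tuple[int, int] = (4, 10)
    n_hbd: tuple[int, int] = (0, 5)
    n_rings: tuple[int, int] = (4, 5)  # SSSR count

    def __post_init__(self) -> None:
        for name in ("mw", "tpsa", "logp", "n_rotatable", "n_hba", "n_hbd", "n_rings"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"window {name}: lower bound {lo} exceeds upper {hi}")


@dataclass
class StericFilterConfig:
    receptor_atoms: list[tuple[str, float, float, float]]
    tolerance: float = 1.5  # Å subtracted from each receptor vdW radius

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


def _load_yaml_patterns() -> dict:
    with resources.files("tkscreen.data").joinpath("pharmacophore_smarts.yaml").open() as fh:
        return yaml.safe_load(fh)


def _load_vdw() -> dict:
    with resources.files("tkscreen.data").joinpath("vdw_radii.json").open() as fh:
        return json.load(fh)


_PATTERNS: Optional[dict[str, list[Chem.Mol]]] = None


def _patterns() -> dict[str, list[Chem.Mol]]:
    global _PATTERNS
    if _PATTERNS is None:
        raw = _load_yaml_patterns()
        _PATTERNS = {
            key: [Chem.MolFromSmarts(s) for s in raw[key]]
            for key in ("hac", "hdo", "pos", "neg")
        }
        for key, mols in _PATTERNS.items():
            if any(m is None for m in mols):
                raise RuntimeError(f"invalid SMARTS in shipped pattern set: {key}")
    return _PATTERNS


def _match_atoms(mol: Chem.Mol, patterns: Sequence[Chem.Mol]) -> set[int]:
    hits: set[int] = set()
    for patt in patterns:
        for match in mol.GetSubstructMatches(patt):
            hits.add(match[0])
    return hits


def perceive_features(compound: CompoundRecord) -> list[PharmacophoreFeature]:
    """Perceive typed features from a compound with an explicit conformer.

    HAC/HDO/POS/NEG sit on qualifying atoms; ARO at centroids of aromatic
    rings; HPB at centroids of connected non-aromatic carbon fragments of
    three or more atoms none of which touches a heteroatom.
    """
    if compound.conformer is None or compound.bonds is None:
        raise ChemIOError(f"compound {compound.id!r} needs conformer and bonds")
    mol = compound.to_mol()
    xyz = compound.coords()
    pats = _patterns()
    features: list[PharmacophoreFeature] = []

    kind_by_pattern = [
        (FeatureKind.HAC, pats["hac"]),
        (FeatureKind.HDO, pats["hdo"]),
        (FeatureKind.POS, pats["pos"]),
        (FeatureKind.NEG, pats["neg"]),
    ]
    for kind, patterns in kind_by_pattern:
        for idx in sorted(_match_atoms(mol, patterns)):
            features.append(PharmacophoreFeature(kind=kind, center=tuple(xyz[idx])))

    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            centroid = xyz[list(ring)].mean(axis=0)
            features.append(PharmacophoreFeature(kind=FeatureKind.ARO, center=tuple(centroid)))

    # hydrophobic fragments: connected non-aromatic carbons with no heteroatom contact
    apolar: set[int] = set()
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C" or atom.GetIsAromatic():
            continue
        if all(nb.GetAtomicNum() in (1, 6) for nb in atom.GetNeighbors()):
            apolar.add(atom.GetIdx())
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(apolar)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in apolar and j in apolar:
            g.add_edge(i, j)
    for comp in sorted(nx.connected_components(g), key=min):
        if len(comp) >= 3:
            centroid = xyz[sorted(comp)].mean(axis=0)
            features.append(PharmacophoreFeature(kind=FeatureKind.HPB, center=tuple(centroid)))
    return features


def model_from_features(
    name: str, features: Sequence[PharmacophoreFeature], required_count: Optional[int] = None
) -> PharmacophoreModel:
    return PharmacophoreModel(name=name, features=list(features), required_count=required_count)


def _fit_rigid(model_pts: np.ndarray, lig_pts: np.ndarray):
    """Least-squares rigid motion taking ligand points onto model points."""
    mc, lc = model_pts.mean(axis=0), lig_pts.mean(axis=0)
    rot, _ = Rotation.align_vectors(model_pts - mc, lig_pts - lc)
    moved = rot.apply(lig_pts - lc) + mc
    return moved, rot.as_matrix(), mc - rot.apply(lc)


def match_model(
    model: PharmacophoreModel,
    ligand_features: Sequence[PharmacophoreFeature],
    allow_alignment: bool = True,
    ligand_id: str = "",
) -> Optional[MatchResult]:
    """Search kind-compatible correspondences; return the lowest-RMSD match.

    Candidate assignments are pruned by pairwise-distance compatibility
    (model inter-feature distances must agree with ligand distances within
    the sum of the two feature radii) and capped at ``ASSIGNMENT_CAP``;
    hitting the cap without an accepting match yields an ``inconclusive``
    no-match.  An accepting correspondence places every matched ligand
    feature within its model sphere after the (optional) alignment.
    """
    lig_by_kind: dict[FeatureKind, list[int]] = {}
    for j, f in enumerate(ligand_features):
        lig_by_kind.setdefault(f.kind, []).append(j)

    lig_xyz = np.array([f.xyz for f in ligand_features]) if ligand_features else np.empty((0, 3))
    best: Optional[MatchResult] = None
    attempts = 0
    capped = False
    req = model.required_count or len(model.features)

    for subset in itertools.combinations(range(len(model.features)), req):
        mod_feats = [model.features[i] for i in subset]
        mod_xyz = np.array([f.xyz for f in mod_feats])
        mod_dists = np.linalg.norm(mod_xyz[:, None, :] - mod_xyz[None, :, :], axis=-1)

        def backtrack(pos: int, assigned: list[int]):
            nonlocal best, attempts, capped
            if capped:
                return
            if pos == len(mod_feats):
                attempts += 1
                if attempts > ASSIGNMENT_CAP:
                    capped = True
                    return
                pts = lig_xyz[assigned]
                if allow_alignment:
                    moved, rotmat, trans = _fit_rigid(mod_xyz, pts)
                else:
                    moved, rotmat, trans = pts, None, None
                sep = np.linalg.norm(moved - mod_xyz, axis=1)
                radii = np.array([f.radius for f in mod_feats])
                if np.all(sep <= radii + 1e-9):
                    rmsd = float(np.sqrt((sep**2).mean()))
                    if best is None or rmsd < best.feature_rmsd:
                        best = MatchResult(
                            ligand_id=ligand_id,
                            correspondence={subset[k]: assigned[k] for k in range(len(assigned))},
                            feature_rmsd=rmsd,
                            rotation=rotmat,
                            translation=trans,
                        )
                return
            target = mod_feats[pos]
            for j in lig_by_kind.get(target.kind, []):
                if j in assigned:
                    continue
                if not allow_alignment:
                    # in-place: prune on absolute position
                    if np.linalg.norm(lig_xyz[j] - mod_xyz[pos]) > target.radius + 1e-9:
                        continue
                ok = True
                if allow_alignment:
                    for k, prev in enumerate(assigned):
                        d_lig = float(np.linalg.norm(lig_xyz[j] - lig_xyz[prev]))
                        tol = target.radius + mod_feats[k].radius
                        if abs(d_lig - mod_dists[pos, k]) > tol:
                            ok = False
                            break
                if ok:
                    backtrack(pos + 1, assigned + [j])

        backtrack(0, [])
        if capped:
            break

    if best is None and capped:
        return MatchResult(
            ligand_id=ligand_id, correspondence={}, feature_rmsd=math.inf, inconclusive=True
        )
    return best


def compute_properties(compound: CompoundRecord) -> dict[str, float]:
    """Drug-likeness descriptors under this package's fixed conventions:
    MW (average masses), Ertl TPSA, Crippen logP, strict rotatable bonds,
    SMARTS-counted acceptors/donors (same patterns as HAC/HDO), SSSR rings."""
    mol = Chem.MolFromSmiles(compound.smiles) if compound.smiles else None
    if mol is None:
        try:
            mol = compound.to_mol()
        except ChemIOError as exc:
            raise ChemIOError(f"cannot compute properties: {exc}") from exc
    pats = _patterns()
    return {
        "mw": float(Descriptors.MolWt(mol)),
        "tpsa": float(Descriptors.TPSA(mol)),
        "logp": float(Crippen.MolLogP(mol)),
        "n_rotatable": int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        "n_hba": len(_match_atoms(mol, pats["hac"])),
        "n_hbd": len(_match_atoms(mol, pats["hdo"])),
        "n_rings": int(rdMolDescriptors.CalcNumRings(mol)),
    }


def property_filter(
    compound: CompoundRecord, window: PropertyWindow | None = None
) -> tuple[bool, dict[str, bool]]:
    """True iff every descriptor lies inside its inclusive window."""
    win = window or PropertyWindow()
    props = compute_properties(compound)
    verdicts = {}
    for name, value in props.items():
        lo, hi = getattr(win, name)
        verdicts[name] = lo <= value <= hi
    return all(verdicts.values()), verdicts


def steric_filter(pose: CompoundRecord, config: StericFilterConfig) -> bool:
    """Accept unless a ligand heavy atom sits within (vdW radius − tolerance)
    of a receptor atom (threshold floored at 0); pose must share the
    receptor's coordinate frame."""
    if not config.receptor_atoms:
        raise ValueError("empty receptor atom list")
    vdw = _load_vdw()
    lig = pose.coords()
    for sym, x, y, z in config.receptor_atoms:
        r = vdw.get(sym, vdw["default"])
        threshold = max(r - config.tolerance, 0.0)
        if threshold == 0.0:
            continue
        d = np.linalg.norm(lig - np.array([x, y, z]), axis=1)
        if np.any(d < threshold):
            return False
    return True


def rank_hits(matches: Sequence[MatchResult]) -> list[MatchResult]:
    """Ascending feature RMSD; ties broken by ligand id."""
    return sorted(matches, key=lambda m: (m.feature_rmsd, m.ligand_id))


def consensus_features(
    aligned_actives: Sequence[Sequence[PharmacophoreFeature]],
    min_support: float = 0.5,
    merge_radius: float = 1.0,
    name: str = "consensus",
) -> PharmacophoreModel:
    """Greedy same-kind clustering of features from co-aligned actives.

    Clusters supported by at least ``min_support`` of the actives become
    model features at the cluster centroid with the kind's default radius.
    """
    if len(aligned_actives) < 2:
        raise ValueError("consensus needs at least 2 active compounds")
    if not 0.0 < min_support <= 1.0:
        raise ValueError("min_support must be in (0, 1]")
    n_actives = len(aligned_actives)
    clusters: list[dict] = []  # {kind, points: [(active_idx, xyz)]}
    for a_idx, feats in enumerate(aligned_actives):
        for f in feats:
            placed = False
            for cl in clusters:
                if cl["kind"] is not f.kind:
                    continue
                centroid = np.mean([p for _i, p in cl["points"]], axis=0)
                if np.linalg.norm(f.xyz - centroid) <= merge_radius:
                    cl["points"].append((a_idx, f.xyz))
                    placed = True
                    break
            if not placed:
                clusters.append({"kind": f.kind, "points": [(a_idx, f.xyz)]})
    kept = []
    for cl in clusters:
        support = len({i for i, _p in cl["points"]}) / n_actives
        if support >= min_support:
            centroid = np.mean([p for _i, p in cl["points"]], axis=0)
            kept.append(
                PharmacophoreFeature(kind=cl["kind"], center=tuple(centroid.tolist()))
            )
    return PharmacophoreModel(name=name, features=kept)
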