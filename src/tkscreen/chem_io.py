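"""Readers/writers for the chemical and tabular formats the pipeline touches.

Canonical in-memory records:

* :class:`CompoundRecord` — a small molecule (SMILES and/or an explicit
  heavy-atom conformer with a bond table).
* :class:`DockingRecord` — one ligand scored against one target by a
  GNINA-style docking run: empirical binding affinity (kcal/mol, more
  negative is stronger), a CNN pose score in [0, 1] (probability that the
  pose is near the reference geometry), and a CNN affinity (unitless,
  positive, higher is stronger).
* :class:`ScoreTable` — a validated collection of docking records.

Conventions: coordinates are Å in a right-handed frame; atom indices are
0-based internally (1-based only inside SDF bond blocks); hydrogens are
dropped on read everywhere — all pose statistics downstream are heavy-atom
statistics.  CSV is comma-separated UTF-8 with a header; the Unicode minus
(U+2212) that appears in typeset tables is normalized to ASCII on read.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

RDLogger.DisableLog("rdApp.*")

SCORE_COLUMNS = ("ligand_id", "target_id", "affinity", "cnn_pose_score", "cnn_affinity")

#: bond order codes used in ``CompoundRecord.bonds`` (SDF V2000 convention)
_BOND_ORDER_TO_RDKIT = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    4: Chem.BondType.AROMATIC,
}
_RDKIT_TO_BOND_ORDER = {v: k for k, v in _BOND_ORDER_TO_RDKIT.items()}


class ChemIOError(ValueError):
    """Raised on malformed chemical input (bad SMILES, bad table, bad pose)."""


@dataclass
class CompoundRecord:
    """One small molecule: identifier, structure, optional 3D heavy-atom pose."""

    id: str
    smiles: str = ""
    conformer: Optional[list[tuple[str, float, float, float]]] = None
    bonds: Optional[list[tuple[int, int, int]]] = None
    charges: Optional[list[int]] = None  # formal charges, parallel to conformer
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ChemIOError("CompoundRecord.id must be non-empty")
        if self.conformer is not None:
            for sym, x, y, z in self.conformer:
                if not all(math.isfinite(v) for v in (x, y, z)):
                    raise ChemIOError(f"non-finite coordinate in record {self.id!r}")
            n = len(self.conformer)
            for i, j, _order in self.bonds or []:
                if not (0 <= i < n and 0 <= j < n):
                    raise ChemIOError(
                        f"bond ({i},{j}) references invalid atom index in record {self.id!r}"
                    )

    @property
    def n_heavy_atoms(self) -> int:
        if self.conformer is not None:
            return len(self.conformer)
        mol = self.to_mol()
        return mol.GetNumHeavyAtoms()

    def coords(self):
        import numpy as np

        if self.conformer is None:
            raise ChemIOError(f"record {self.id!r} has no conformer")
        return np.array([[x, y, z] for _s, x, y, z in self.conformer], dtype=float)

    def to_mol(self) -> Chem.Mol:
        """Build an RDKit molecule, preferring the explicit conformer+bonds."""
        if self.conformer is not None and self.bonds is not None:
            rw = Chem.RWMol()
            for k, (sym, *_xyz) in enumerate(self.conformer):
                atom = Chem.Atom(sym)
                if self.charges is not None:
                    atom.SetFormalCharge(self.charges[k])
                rw.AddAtom(atom)
            for i, j, order in self.bonds:
                rw.AddBond(i, j, _BOND_ORDER_TO_RDKIT.get(order, Chem.BondType.SINGLE))
            conf = Chem.Conformer(len(self.conformer))
            for idx, (_sym, x, y, z) in enumerate(self.conformer):
                conf.SetAtomPosition(idx, Point3D(x, y, z))
            mol = rw.GetMol()
            mol.AddConformer(conf)
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                # toy poses need not be valence-perfect; keep the raw graph
                mol.UpdatePropertyCache(strict=False)
                Chem.FastFindRings(mol)
            return mol
        if self.smiles:
            mol = Chem.MolFromSmiles(self.smiles)
            if mol is None:
                raise ChemIOError(f"unparsable SMILES for record {self.id!r}: {self.smiles!r}")
            return mol
        raise ChemIOError(f"record {self.id!r} has neither SMILES nor conformer")


@dataclass(frozen=True)
class DockingRecord:
    """One ligand's (affinity, CNN pose score, CNN affinity) triple for one target."""

    ligand_id: str
    target_id: str
    affinity: float
    cnn_pose_score: float
    cnn_affinity: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.affinity):
            raise ChemIOError(f"{self.ligand_id}/{self.target_id}: affinity not finite")
        if not 0.0 <= self.cnn_pose_score <= 1.0:
            raise ChemIOError(
                f"{self.ligand_id}/{self.target_id}: cnn_pose_score "
                f"{self.cnn_pose_score} outside [0, 1]"
            )
        if not (math.isfinite(self.cnn_affinity) and self.cnn_affinity > 0):
            raise ChemIOError(
                f"{self.ligand_id}/{self.target_id}: cnn_affinity must be positive"
            )


@dataclass
class ScoreTable:
    """Sequence of docking records with unique (ligand, target) pairs."""

    records: list[DockingRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            key = (r.ligand_id, r.target_id)
            if key in seen:
                raise ChemIOError(f"duplicate (ligand, target) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def for_target(self, target_id: str) -> "ScoreTable":
        return ScoreTable(
            [r for r in self.records if r.target_id == target_id],
            provenance=f"{self.provenance} [target={target_id}]",
        )

    @property
    def targets(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.target_id not in out:
                out.append(r.target_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records], columns=SCORE_COLUMNS)


def _normalize_minus(text: str) -> str:
    # typeset tables use U+2212; also seen: en-dash used as a minus
    return text.replace("−", "-").replace("–", "-")


def read_smiles_library(path: str | Path) -> list[CompoundRecord]:
    """Read a one-record-per-line ``SMILES <whitespace> id`` library.

    Every line must parse; offenders are reported with their 1-based line
    numbers.  SMILES are canonicalized on read.  Blank lines are skipped.
    """
    path = Path(path)
    records: list[CompoundRecord] = []
    bad_lines: list[str] = []
    seen_ids: set[str] = set()
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            bad_lines.append(f"line {lineno}: expected 'SMILES id', got {raw!r}")
            continue
        smiles, cid = parts
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            bad_lines.append(f"line {lineno}: unparsable SMILES {smiles!r}")
            continue
        if cid in seen_ids:
            raise ChemIOError(f"duplicate compound id {cid!r} at line {lineno}")
        seen_ids.add(cid)
        records.append(CompoundRecord(id=cid, smiles=Chem.MolToSmiles(mol)))
    if bad_lines:
        raise ChemIOError("malformed SMILES library:\n" + "\n".join(bad_lines))
    return records


def write_smiles_library(records: Iterable[CompoundRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.smiles} {rec.id}\n")


def read_score_table(path: str | Path) -> ScoreTable:
    """Read a docking-score CSV (ligand_id, target_id, affinity, cnn_pose_score,
    cnn_affinity); every row is validated against the DockingRecord invariants."""
    path = Path(path)
    text = _normalize_minus(path.read_text(encoding="utf-8"))
    reader = csv.DictReader(text.splitlines())
    if reader.fieldnames is None:
        raise ChemIOError(f"{path}: empty file, expected a CSV header")
    missing = [c for c in SCORE_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise ChemIOError(f"{path}: missing column(s) {', '.join(missing)}")
    records = []
    for rownum, row in enumerate(reader, start=2):
        try:
            records.append(
                DockingRecord(
                    ligand_id=row["ligand_id"].strip(),
                    target_id=row["target_id"].strip(),
                    affinity=float(row["affinity"]),
                    cnn_pose_score=float(row["cnn_pose_score"]),
                    cnn_affinity=float(row["cnn_affinity"]),
                )
            )
        except (ChemIOError, ValueError) as exc:
            raise ChemIOError(f"{path} row {rownum}: {exc}") from exc
    return ScoreTable(records, provenance=str(path))


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCORE_COLUMNS)
        for r in table.records:
            writer.writerow(
                [r.ligand_id, r.target_id, repr(r.affinity), repr(r.cnn_pose_score), repr(r.cnn_affinity)]
            )


def _record_from_mol(mol: Chem.Mol, rec_id: str) -> CompoundRecord:
    mol = Chem.RemoveHs(mol, sanitize=False)
    mol.UpdatePropertyCache(strict=False)
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    index_map = {old: new for new, old in enumerate(heavy)}
    conf = mol.GetConformer()
    conformer = []
    charges = []
    for old in heavy:
        pos = conf.GetAtomPosition(old)
        conformer.append((mol.GetAtomWithIdx(old).GetSymbol(), pos.x, pos.y, pos.z))
        charges.append(mol.GetAtomWithIdx(old).GetFormalCharge())
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in index_map and j in index_map:
            order = _RDKIT_TO_BOND_ORDER.get(b.GetBondType(), 1)
            bonds.append((index_map[i], index_map[j], order))
    try:
        smiles = Chem.MolToSmiles(Chem.Mol(mol))
    except Exception:
        smiles = ""
    return CompoundRecord(
        id=rec_id,
        smiles=smiles,
        conformer=conformer,
        bonds=bonds,
        charges=charges if any(charges) else None,
    )


def read_pose(path: str | Path, format: Optional[str] = None, index: Optional[int] = None) -> CompoundRecord:
    """Read one ligand pose from an SDF (V2000) or PDB (HETATM) file.

    Hydrogens are dropped.  A multi-molecule SDF requires an explicit
    ``index`` (0-based); a PDB file must contain HETATM records.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("sdf", "mol", "sd"):
        text = path.read_text(encoding="utf-8")
        if "V3000" in text:
            raise ChemIOError(f"{path}: V3000 SDF not supported, re-export as V2000")
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        mols = [m for m in supplier if m is not None]
        if not mols:
            raise ChemIOError(f"{path}: no parsable molecule in SDF")
        if len(mols) > 1 and index is None:
            raise ChemIOError(
                f"{path}: SDF holds {len(mols)} molecules; pass index to select one"
            )
        mol = mols[index or 0]
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else path.stem
        return _record_from_mol(mol, name)
    if fmt == "pdb":
        het_lines = [
            ln
            for ln in path.read_text(encoding="utf-8").splitlines()
            if ln.startswith("HETATM") and ln[17:20].strip() != "HOH"
        ]
        if not het_lines:
            raise ChemIOError(f"{path}: no HETATM records (ligand extraction only)")
        block = "\n".join(het_lines) + "\nEND\n"
        mol = Chem.MolFromPDBBlock(block, sanitize=False, removeHs=False, proximityBonding=True)
        if mol is None:
            raise ChemIOError(f"{path}: could not parse HETATM records")
        return _record_from_mol(mol, path.stem)
    raise ChemIOError(f"unsupported pose format {fmt!r} (use sdf or pdb)")


def write_pose(record: CompoundRecord, path: str | Path) -> None:
    """Write a conformer as a single-molecule SDF V2000 file."""
    if record.conformer is None:
        raise ChemIOError(f"record {record.id!r} has no conformer to write")
    mol = record.to_mol()
    mol.SetProp("_Name", record.id)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    writer.write(mol)
    writer.close()
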