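"""2D fingerprint similarity and similarity-based target-hypothesis generation.

A query compound inherits the annotated kinase targets of any reference drug
it resembles under *both* of two fingerprint views simultaneously:

* MACCS substructure keys (the public 166-key dictionary, via RDKit);
* Carhart-style atom pairs — key = (atom type, atom type, topological
  shortest-path distance) with atom type = (element, heavy-neighbor count,
  aromatic flag); distances are capped at 30 bonds; set membership only.

Similarity is the Tanimoto coefficient Tani = c / (a + b − c), where a and b
count the on-bits of each structure and c the shared on-bits.  The dual gate
passes when Tani_AP ≥ 0.237 and Tani_MACCS ≥ 0.528 simultaneously
(inclusive); both defaults are configurable.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit.Chem import MACCSkeys

from .chem_io import CompoundRecord

#: default dual-gate thresholds (derived upstream from a 90% similarity
#: percentile over FDA-approved drug pairs; taken here as fixed constants)
DEFAULT_AP_MIN = 0.237
DEFAULT_MACCS_MIN = 0.528

_DISTANCE_CAP = 30


class FingerprintScheme(enum.Enum):
    SUBSTRUCTURE_KEYS_166 = "maccs"
    ATOM_PAIRS = "atom_pairs"


class SimilarityError(ValueError):
    pass


@dataclass(frozen=True)
class Fingerprint:
    scheme: FingerprintScheme
    bits: frozenset[int]

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class TanimotoScore:
    """Tanimoto coefficient with its defining counts: value = c/(a+b−c)."""

    a: int
    b: int
    c: int
    value: float


@dataclass(frozen=True)
class SimilarityGateConfig:
    ap_min: float = DEFAULT_AP_MIN
    maccs_min: float = DEFAULT_MACCS_MIN
    inclusive: bool = True

    def __post_init__(self) -> None:
        for v in (self.ap_min, self.maccs_min):
            if not 0.0 <= v <= 1.0:
                raise SimilarityError(f"gate threshold {v} outside [0, 1]")


@dataclass(frozen=True)
class TargetHypothesis:
    """A (compound, drug) pair that passed the gate, carrying the drug's targets."""

    compound_id: str
    drug_id: str
    tani_ap: float
    tani_maccs: float
    proposed_targets: frozenset[str]


def _atom_type(atom: Chem.Atom) -> int:
    heavy_deg = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)
    return atom.GetAtomicNum() * 100 + heavy_deg * 10 + int(atom.GetIsAromatic())


def _atom_pair_bits(mol: Chem.Mol) -> frozenset[int]:
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if len(heavy) < 2:
        return frozenset()
    dist = Chem.GetDistanceMatrix(mol)
    bits: set[int] = set()
    for ii in range(len(heavy)):
        for jj in range(ii + 1, len(heavy)):
            ai, aj = heavy[ii], heavy[jj]
            d = int(dist[ai.GetIdx(), aj.GetIdx()])
            d = min(d, _DISTANCE_CAP)
            t_lo, t_hi = sorted((_atom_type(ai), _atom_type(aj)))
            bits.add(t_lo * 1_000_000 + t_hi * 100 + d)
    return frozenset(bits)


def compute_fingerprint(compound: CompoundRecord, scheme: FingerprintScheme) -> Fingerprint:
    """Fingerprint a compound; equal canonical SMILES give equal fingerprints."""
    mol = Chem.MolFromSmiles(compound.smiles) if compound.smiles else None
    if mol is None:
        raise SimilarityError(f"unparsable structure for compound {compound.id!r}")
    if scheme is FingerprintScheme.SUBSTRUCTURE_KEYS_166:
        bv = MACCSkeys.GenMACCSKeys(mol)  # bit 0 unused; keys live at 1..166
        bits = frozenset(b - 1 for b in bv.GetOnBits() if b >= 1)
    elif scheme is FingerprintScheme.ATOM_PAIRS:
        bits = _atom_pair_bits(mol)
    else:  # pragma: no cover
        raise SimilarityError(f"unknown scheme {scheme}")
    return Fingerprint(scheme=scheme, bits=bits)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> TanimotoScore:
    """Tanimoto coefficient c/(a+b−c) between two same-scheme fingerprints.

    Two empty fingerprints are defined to have similarity 0.0 (featureless
    structures are not considered similar); a warning is emitted.
    """
    if fp_a.scheme is not fp_b.scheme:
        raise SimilarityError(f"scheme mismatch: {fp_a.scheme} vs {fp_b.scheme}")
    a, b = len(fp_a.bits), len(fp_b.bits)
    c = len(fp_a.bits & fp_b.bits)
    if a == 0 and b == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0.0", stacklevel=2)
        return TanimotoScore(a=0, b=0, c=0, value=0.0)
    return TanimotoScore(a=a, b=b, c=c, value=c / (a + b - c))


def similarity_gate(
    tani_ap: float, tani_maccs: float, config: SimilarityGateConfig | None = None
) -> bool:
    """True iff both Tanimoto values meet their thresholds (inclusive by default)."""
    cfg = config or SimilarityGateConfig()
    for v in (tani_ap, tani_maccs):
        if not 0.0 <= v <= 1.0:
            raise SimilarityError(f"Tanimoto value {v} outside [0, 1]")
    if cfg.inclusive:
        return tani_ap >= cfg.ap_min and tani_maccs >= cfg.maccs_min
    return tani_ap > cfg.ap_min and tani_maccs > cfg.maccs_min


def propose_targets(
    query_library: Sequence[CompoundRecord],
    drug_library: Sequence[CompoundRecord],
    drug_target_map: Mapping[str, Iterable[str]],
    config: SimilarityGateConfig | None = None,
) -> list[TargetHypothesis]:
    """Generate target hypotheses for every (query, drug) pair passing the gate.

    Output is sorted by descending atom-pair Tanimoto, then descending MACCS
    Tanimoto, then drug id — a deterministic ranking.
    """
    cfg = config or SimilarityGateConfig()
    unmapped = [d.id for d in drug_library if d.id not in drug_target_map]
    if unmapped:
        raise SimilarityError(f"drug(s) missing from target map: {', '.join(unmapped)}")
    drug_fps = [
        (
            drug,
            compute_fingerprint(drug, FingerprintScheme.ATOM_PAIRS),
            compute_fingerprint(drug, FingerprintScheme.SUBSTRUCTURE_KEYS_166),
        )
        for drug in drug_library
    ]
    hypotheses: list[TargetHypothesis] = []
    for query in query_library:
        q_ap = compute_fingerprint(query, FingerprintScheme.ATOM_PAIRS)
        q_maccs = compute_fingerprint(query, FingerprintScheme.SUBSTRUCTURE_KEYS_166)
        for drug, d_ap, d_maccs in drug_fps:
            t_ap = tanimoto(q_ap, d_ap).value
            t_maccs = tanimoto(q_maccs, d_maccs).value
            if similarity_gate(t_ap, t_maccs, cfg):
                hypotheses.append(
                    TargetHypothesis(
                        compound_id=query.id,
                        drug_id=drug.id,
                        tani_ap=t_ap,
                        tani_maccs=t_maccs,
                        proposed_targets=frozenset(drug_target_map[drug.id]),
                    )
                )
    hypotheses.sort(key=lambda h: (-h.tani_ap, -h.tani_maccs, h.drug_id))
    return hypotheses


def read_drug_target_map(path) -> dict[str, set[str]]:
    """Read a drug→target reference mapping CSV with columns drug_id, target_id."""
    import csv as _csv
    from pathlib import Path as _Path

    out: dict[str, set[str]] = {}
    with open(_Path(path), encoding="utf-8") as fh:
        reader = _csv.DictReader(fh)
        if reader.fieldnames is None or not {"drug_id", "target_id"} <= set(reader.fieldnames):
            raise SimilarityError(f"{path}: expected columns drug_id, target_id")
        for row in reader:
            out.setdefault(row["drug_id"].strip(), set()).add(row["target_id"].strip())
    return out
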