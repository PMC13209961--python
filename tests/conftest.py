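import math

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from tkscreen.chem_io import CompoundRecord, DockingRecord, ScoreTable


@pytest.fixture()
def benzene_ring() -> CompoundRecord:
    """Planar benzene heavy-atom conformer (unit hexagon, aromatic bonds)."""
    conf = [
        ("C", math.cos(math.radians(60 * i)), math.sin(math.radians(60 * i)), 0.0)
        for i in range(6)
    ]
    bonds = [(i, (i + 1) % 6, 4) for i in range(6)]
    return CompoundRecord(id="benzene", smiles="c1ccccc1", conformer=conf, bonds=bonds)


@pytest.fixture()
def toy_chain() -> CompoundRecord:
    """Asymmetric, non-collinear 4-atom chain C-C-N-O (no non-trivial automorphism)."""
    conf = [("C", 0.0, 0.0, 0.0), ("C", 1.5, 0.0, 0.0), ("N", 2.3, 1.2, 0.0), ("O", 3.1, 1.6, 1.1)]
    bonds = [(0, 1, 1), (1, 2, 1), (2, 3, 1)]
    return CompoundRecord(id="chain", conformer=conf, bonds=bonds)


def translated(record: CompoundRecord, dx=0.0, dy=0.0, dz=0.0) -> CompoundRecord:
    return CompoundRecord(
        id=record.id + "-t",
        smiles=record.smiles,
        conformer=[(s, x + dx, y + dy, z + dz) for s, x, y, z in record.conformer],
        bonds=list(record.bonds),
    )


@pytest.fixture()
def small_score_table() -> ScoreTable:
    return ScoreTable(
        [
            DockingRecord("lig1", "KIN1", -10.0, 0.9, 8.0),
            DockingRecord("lig2", "KIN1", -8.0, 0.7, 7.2),
            DockingRecord("lig3", "KIN2", -9.0, 0.8, 7.6),
        ],
        provenance="fixture",
    )
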