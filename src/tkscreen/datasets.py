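"""Reference tables shipped with the package.

* ``fda_benchmark.csv`` — docking scores (affinity kcal/mol, CNN pose
  score, CNN affinity) of 48 FDA-approved kinase-inhibitor/target pairs
  across ten kinases; the benchmark from which acceptance thresholds are
  derived.
* ``crossdock_rmsd.csv`` — cross-docking results for 25 approved drugs:
  the same three scores plus the heavy-atom RMSD (Å) to the co-crystal
  pose.
* ``vs_hits.csv`` — score triples of virtual-screening hit compounds per
  kinase target, used to exercise the triage rule.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .chem_io import DockingRecord, ScoreTable


def _data_path(name: str):
    return resources.files("tkscreen.data").joinpath(name)


def _read_scores(name: str) -> ScoreTable:
    with _data_path(name).open() as fh:
        frame = pd.read_csv(fh)
    records = [
        DockingRecord(
            ligand_id=row.ligand_id,
            target_id=row.target_id,
            affinity=float(row.affinity),
            cnn_pose_score=float(row.cnn_pose_score),
            cnn_affinity=float(row.cnn_affinity),
        )
        for row in frame.itertuples()
    ]
    return ScoreTable(records, provenance=name)


def load_fda_benchmark() -> ScoreTable:
    """FDA-approved kinase-inhibitor benchmark (48 drug/target score triples)."""
    return _read_scores("fda_benchmark.csv")


def load_vs_hits(target_id: str | None = None) -> ScoreTable:
    """Virtual-screening hit score triples, optionally restricted to one target."""
    table = _read_scores("vs_hits.csv")
    return table.for_target(target_id) if target_id else table


def load_crossdock_rmsd() -> pd.DataFrame:
    """Cross-docking scores and RMSD values for approved drugs (DataFrame)."""
    with _data_path("crossdock_rmsd.csv").open() as fh:
        return pd.read_csv(fh)
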