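"""End-to-end pipeline driver: similarity → thresholds → triage → validation
→ pharmacophore screen, with a machine-readable run manifest.

Stages are composable: only the stages whose inputs appear in the config
run; the manifest records which branch was active.  All randomness flows
from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .benchmark_stats import ThresholdConfig, category_override, derive_thresholds
from .chem_io import read_score_table, read_smiles_library
from .pharmacophore import (
    PharmacophoreModel,
    PropertyWindow,
    match_model,
    perceive_features,
    property_filter,
    rank_hits,
)
from .chem_io import read_pose
from .screen_metrics import enrichment_factor, roc_auc
from .similarity import SimilarityGateConfig, propose_targets, read_drug_target_map
from .triage import decisions_frame, triage_table

log = logging.getLogger("tkscreen")


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    # similarity stage
    query_library: Optional[Path] = None
    drug_library: Optional[Path] = None
    drug_target_map: Optional[Path] = None
    ap_min: float = 0.237
    maccs_min: float = 0.528
    # thresholds stage
    benchmark: Optional[Path] = None
    alpha: float = 0.05
    overrides: dict[str, Optional[float]] = field(default_factory=dict)  # target -> value|None(=mean)
    # triage stage
    candidates: Optional[Path] = None
    # validation stage
    screen_scores: Optional[Path] = None  # CSV: id,score,active
    top_pct: float = 5.0
    # pharmacophore stage
    pharmacophore_model: Optional[Path] = None
    screen_library: Optional[list[Path]] = None  # SDF poses
    apply_property_window: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        out_dir = Path(raw.pop("out_dir"))
        cfg = cls(out_dir=out_dir)
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key.endswith(("library", "map", "benchmark", "candidates", "scores", "model")):
                value = Path(value)
            if key == "screen_library":
                value = [Path(p) for p in raw[key]]
            setattr(cfg, key, value)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _require(stage: str, path: Optional[Path]) -> Path:
    if path is None or not Path(path).exists():
        raise StageError(stage, f"missing input file: {path}")
    return Path(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage whose inputs are configured; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "tkscreen",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    if config.query_library is not None:
        log.info("stage: similarity")
        queries = read_smiles_library(_require("similarity", config.query_library))
        drugs = read_smiles_library(_require("similarity", config.drug_library))
        target_map = read_drug_target_map(_require("similarity", config.drug_target_map))
        gate = SimilarityGateConfig(ap_min=config.ap_min, maccs_min=config.maccs_min)
        hypotheses = propose_targets(queries, drugs, target_map, gate)
        import pandas as pd

        frame = pd.DataFrame(
            [
                {
                    "compound_id": h.compound_id,
                    "drug_id": h.drug_id,
                    "tani_ap": h.tani_ap,
                    "tani_maccs": h.tani_maccs,
                    "proposed_targets": "|".join(sorted(h.proposed_targets)),
                }
                for h in hypotheses
            ],
            columns=["compound_id", "drug_id", "tani_ap", "tani_maccs", "proposed_targets"],
        )
        dest = out / "hypotheses.csv"
        frame.to_csv(dest, index=False)
        manifest["stages"]["similarity"] = {"n_hypotheses": len(hypotheses)}
        manifest["outputs"]["hypotheses"] = dest.name

    thresholds = None
    if config.benchmark is not None:
        log.info("stage: thresholds")
        bench = read_score_table(_require("thresholds", config.benchmark))
        thresholds = derive_thresholds(bench, ThresholdConfig(alpha=config.alpha))
        for target, value in config.overrides.items():
            if value is None:
                category_override(bench, target, thresholds)
            else:
                thresholds.category_overrides[target] = float(value)
        dest = out / "thresholds.json"
        thresholds.to_json(dest)
        manifest["stages"]["thresholds"] = thresholds.rounded()
        manifest["outputs"]["thresholds"] = dest.name

    if config.candidates is not None:
        if thresholds is None:
            raise StageError("triage", "no thresholds available (configure a benchmark)")
        log.info("stage: triage")
        cand = read_score_table(_require("triage", config.candidates))
        report = triage_table(cand, thresholds)
        dest = out / "triage.csv"
        decisions_frame(report).to_csv(dest, index=False)
        manifest["stages"]["triage"] = {
            "n_candidates": len(report.decisions),
            "n_accepted": report.n_accepted,
        }
        manifest["outputs"]["triage"] = dest.name

    if config.screen_scores is not None:
        log.info("stage: validation metrics")
        import pandas as pd

        frame = pd.read_csv(_require("metrics", config.screen_scores))
        scores = [
            (str(r.id), float(r.score), bool(r.active)) for r in frame.itertuples()
        ]
        ef = enrichment_factor(scores, x_pct=config.top_pct)
        roc = roc_auc(scores)
        dest = out / "metrics.json"
        payload = {
            "ef": ef.ef,
            "auc": roc.auc,
            "counts": ef.input.__dict__,
        }
        dest.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        manifest["stages"]["metrics"] = {"ef": ef.ef, "auc": roc.auc}
        manifest["outputs"]["metrics"] = dest.name

    if config.pharmacophore_model is not None:
        log.info("stage: pharmacophore screen")
        model = PharmacophoreModel.from_json(_require("pharma", config.pharmacophore_model))
        matches = []
        n_screened = 0
        for pose_path in config.screen_library or []:
            record = read_pose(_require("pharma", pose_path))
            n_screened += 1
            if config.apply_property_window:
                ok, _verdicts = property_filter(record, PropertyWindow())
                if not ok:
                    continue
            feats = perceive_features(record)
            m = match_model(model, feats, allow_alignment=True, ligand_id=record.id)
            if m is not None and not m.inconclusive:
                matches.append(m)
        import pandas as pd

        ranked = rank_hits(matches)
        frame = pd.DataFrame(
            [{"ligand_id": m.ligand_id, "feature_rmsd": m.feature_rmsd} for m in ranked],
            columns=["ligand_id", "feature_rmsd"],
        )
        dest = out / "pharmacophore_hits.csv"
        frame.to_csv(dest, index=False)
        manifest["stages"]["pharmacophore"] = {"n_screened": n_screened, "n_hits": len(ranked)}
        manifest["outputs"]["pharmacophore_hits"] = dest.name

    manifest["config_hash"] = hashlib.sha256(
        json.dumps(
            {k: str(v) for k, v in vars(config).items()}, sort_keys=True
        ).encode()
    ).hexdigest()
    manifest["timestamp"] = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest
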