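import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

from tkscreen.chem_io import ChemIOError, CompoundRecord, _record_from_mol
from tkscreen.pharmacophore import (
    FeatureKind,
    PharmacophoreFeature,
    PharmacophoreModel,
    PropertyWindow,
    StericFilterConfig,
    consensus_features,
    match_model,
    perceive_features,
    property_filter,
    rank_hits,
    steric_filter,
)


def embedded(smiles: str, name: str = "mol") -> CompoundRecord:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    assert AllChem.EmbedMolecule(mol, randomSeed=11) == 0
    return _record_from_mol(mol, name)


def feat(kind, x, y, z, radius=0.0):
    return PharmacophoreFeature(kind=kind, center=(x, y, z), radius=radius)


class TestPerception:
    def test_benzene_single_aromatic_feature_at_centroid(self, benzene_ring):
        feats = perceive_features(benzene_ring)
        assert [f.kind for f in feats] == [FeatureKind.ARO]
        np.testing.assert_allclose(feats[0].xyz, [0, 0, 0], atol=1e-9)
        assert feats[0].radius == pytest.approx(1.1)

    def test_methane_has_no_features(self):
        rec = embedded("C", "methane")
        assert perceive_features(rec) == []

    def test_pyridine_one_aro_plus_one_hac_on_nitrogen(self):
        rec = embedded("c1ccncc1", "pyridine")
        kinds = sorted(f.kind.value for f in perceive_features(rec))
        assert kinds == ["ARO", "HAC"]

    def test_amide_nitrogen_is_not_an_acceptor_but_carbonyl_oxygen_is(self):
        rec = embedded("CC(=O)NC", "amide")
        kinds = [f.kind for f in perceive_features(rec)]
        assert kinds.count(FeatureKind.HAC) == 1  # the C=O oxygen only
        assert kinds.count(FeatureKind.HDO) == 1  # the N-H

    def test_hydrophobic_fragment_of_three_carbons(self):
        rec = embedded("CCCCO", "butanol")
        feats = perceive_features(rec)
        hpb = [f for f in feats if f.kind is FeatureKind.HPB]
        # only the three carbons away from the hydroxyl qualify
        assert len(hpb) == 1

    def test_charged_atoms_perceived(self):
        rec = embedded("C[N+](C)(C)C", "tma")
        kinds = [f.kind for f in perceive_features(rec)]
        assert FeatureKind.POS in kinds and FeatureKind.NEG not in kinds

    def test_conformer_required(self):
        with pytest.raises(ChemIOError):
            perceive_features(CompoundRecord(id="x", smiles="CCO"))

    def test_deterministic(self):
        rec = embedded("O=C(Nc1ccc(F)cc1)Nc1ccccc1", "urea")
        assert perceive_features(rec) == perceive_features(rec)


class TestMatching:
    def _self_model(self, record):
        feats = perceive_features(record)
        assert len(feats) >= 2
        return PharmacophoreModel(name="self", features=feats), feats

    def test_self_match_rmsd_zero(self):
        rec = embedded("O=C(Nc1ccc(F)cc1)Nc1ccccc1", "urea")
        model, feats = self._self_model(rec)
        m = match_model(model, feats, allow_alignment=False, ligand_id=rec.id)
        assert m is not None and m.feature_rmsd == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 4])
    def test_match_invariant_under_rigid_motion_with_alignment(self, seed):
        rec = embedded("O=C(Nc1ccc(F)cc1)Nc1ccccc1", "urea")
        model, feats = self._self_model(rec)
        rng = np.random.default_rng(seed)
        rot = Rotation.random(random_state=int(rng.integers(2**31)))
        shift = rng.normal(0, 4, 3)
        moved = [
            PharmacophoreFeature(kind=f.kind, center=tuple(rot.apply(f.xyz) + shift))
            for f in feats
        ]
        m = match_model(model, moved, allow_alignment=True, ligand_id=rec.id)
        assert m is not None and m.feature_rmsd == pytest.approx(0.0, abs=1e-6)

    def test_translation_without_alignment_breaks_match(self):
        rec = embedded("O=C(Nc1ccc(F)cc1)Nc1ccccc1", "urea")
        model, feats = self._self_model(rec)
        moved = [
            PharmacophoreFeature(kind=f.kind, center=(f.center[0] + 25.0, f.center[1], f.center[2]))
            for f in feats
        ]
        assert match_model(model, moved, allow_alignment=False) is None

    def test_feature_beyond_radius_gives_no_match(self):
        model = PharmacophoreModel(
            name="m",
            features=[
                feat(FeatureKind.HAC, 0, 0, 0, radius=0.5),
                feat(FeatureKind.HAC, 5, 0, 0, radius=0.5),
            ],
        )
        lig = [feat(FeatureKind.HAC, 0, 0, 0), feat(FeatureKind.HAC, 7.5, 0, 0)]
        assert match_model(model, lig, allow_alignment=True) is None

    def test_missing_kind_gives_no_match(self):
        model = PharmacophoreModel(
            name="m",
            features=[feat(FeatureKind.ARO, 0, 0, 0), feat(FeatureKind.NEG, 3, 0, 0)],
        )
        lig = [feat(FeatureKind.ARO, 0, 0, 0), feat(FeatureKind.HAC, 3, 0, 0)]
        assert match_model(model, lig) is None

    def test_required_count_allows_partial_match(self):
        model = PharmacophoreModel(
            name="m",
            features=[
                feat(FeatureKind.HAC, 0, 0, 0),
                feat(FeatureKind.HAC, 3, 0, 0),
                feat(FeatureKind.ARO, 0, 3, 0),
            ],
            required_count=2,
        )
        lig = [feat(FeatureKind.HAC, 0, 0, 0), feat(FeatureKind.HAC, 3, 0, 0)]
        m = match_model(model, lig, allow_alignment=False)
        assert m is not None and len(m.correspondence) == 2


class TestPropertyFilter:
    def test_mid_window_quinazoline_passes_every_window(self):
        # 4-ring morpholino-quinazoline sitting inside all seven windows
        # (MW 430.9, TPSA 89.0, logP 3.2, 7 rotatable, 7 HBA, 2 HBD, 4 rings)
        rec = CompoundRecord(
            id="mid", smiles="COc1cc2ncnc(Nc3ccc(N4CCOCC4)cc3Cl)c2cc1OCCO"
        )
        ok, verdicts = property_filter(rec)
        assert ok and all(verdicts.values())

    def test_low_mw_fails_on_mw_only_window(self):
        window = PropertyWindow(
            mw=(416.81, 461.47),
            tpsa=(0, 1000),
            logp=(-10, 10),
            n_rotatable=(0, 99),
            n_hba=(0, 99),
            n_hbd=(0, 99),
            n_rings=(0, 99),
        )
        ok, verdicts = property_filter(CompoundRecord(id="small", smiles="c1ccccc1O"), window)
        assert not ok and not verdicts["mw"]
        assert all(v for k, v in verdicts.items() if k != "mw")

    def test_windows_inclusive_at_boundaries(self):
        from tkscreen.pharmacophore import compute_properties

        rec = CompoundRecord(id="x", smiles="O=C(Nc1ccc(F)cc1)Nc1ccccc1")
        props = compute_properties(rec)
        window = PropertyWindow(
            mw=(props["mw"], props["mw"]),
            tpsa=(props["tpsa"], props["tpsa"]),
            logp=(props["logp"], props["logp"]),
            n_rotatable=(props["n_rotatable"], props["n_rotatable"]),
            n_hba=(props["n_hba"], props["n_hba"]),
            n_hbd=(props["n_hbd"], props["n_hbd"]),
            n_rings=(props["n_rings"], props["n_rings"]),
        )
        ok, _ = property_filter(rec, window)
        assert ok

    def test_widening_any_window_never_flips_pass_to_fail(self):
        rec = CompoundRecord(id="x", smiles="COc1cc2ncnc(Nc3ccc(F)cc3)c2cc1OC")
        base = PropertyWindow(
            mw=(0, 1000), tpsa=(0, 500), logp=(-10, 10),
            n_rotatable=(0, 50), n_hba=(0, 50), n_hbd=(0, 50), n_rings=(0, 50),
        )
        assert property_filter(rec, base)[0]
        wider = PropertyWindow(
            mw=(0, 2000), tpsa=(0, 1000), logp=(-20, 20),
            n_rotatable=(0, 99), n_hba=(0, 99), n_hbd=(0, 99), n_rings=(0, 99),
        )
        assert property_filter(rec, wider)[0]

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            PropertyWindow(mw=(500, 400))


class TestStericFilter:
    LIG = CompoundRecord(
        id="probe", conformer=[("C", 0.0, 0.0, 0.0), ("C", 1.5, 0.0, 0.0), ("C", 3.0, 0.0, 0.0)],
        bonds=[(0, 1, 1), (1, 2, 1)],
    )

    def test_atom_inside_reduced_vdw_shell_rejected(self):
        # carbon vdW 1.70, tolerance 1.5 -> clash threshold 0.2 A; 0.1 < 0.2
        cfg = StericFilterConfig(receptor_atoms=[("C", 0.1, 0.0, 0.0)], tolerance=1.5)
        assert steric_filter(self.LIG, cfg) is False

    def test_far_receptor_accepted(self):
        cfg = StericFilterConfig(receptor_atoms=[("C", 10.0, 10.0, 10.0)], tolerance=1.5)
        assert steric_filter(self.LIG, cfg) is True

    def test_tolerance_exceeding_radii_accepts_everything(self):
        cfg = StericFilterConfig(receptor_atoms=[("C", 0.0, 0.0, 0.0)], tolerance=2.5)
        assert steric_filter(self.LIG, cfg) is True

    def test_empty_receptor_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            steric_filter(self.LIG, StericFilterConfig(receptor_atoms=[]))


class TestRankingAndConsensus:
    def _match(self, lid, rmsd):
        from tkscreen.pharmacophore import MatchResult

        return MatchResult(ligand_id=lid, correspondence={}, feature_rmsd=rmsd)

    def test_rank_ascending_rmsd(self):
        ranked = rank_hits([self._match("a", 0.8), self._match("b", 0.2), self._match("c", 0.5)])
        assert [m.ligand_id for m in ranked] == ["b", "c", "a"]

    def test_ties_broken_by_id(self):
        ranked = rank_hits([self._match("z", 0.5), self._match("a", 0.5)])
        assert [m.ligand_id for m in ranked] == ["a", "z"]

    def test_empty_input(self):
        assert rank_hits([]) == []

    def test_identical_sets_full_support(self):
        feats = [feat(FeatureKind.HAC, 0, 0, 0), feat(FeatureKind.ARO, 3, 0, 0)]
        model = consensus_features([feats, feats, feats], min_support=1.0)
        assert model.kind_counts() == {"HAC": 1, "ARO": 1}

    def test_rare_feature_excluded_by_support(self):
        common = [feat(FeatureKind.HAC, 0, 0, 0), feat(FeatureKind.ARO, 3, 0, 0)]
        rare = common + [feat(FeatureKind.HDO, 0, 5, 0)]
        model = consensus_features([common, common, common, rare], min_support=0.5)
        assert "HDO" not in model.kind_counts()

    def test_nearby_same_kind_features_merge_to_centroid(self):
        a = [feat(FeatureKind.HAC, 0.0, 0, 0), feat(FeatureKind.ARO, 5, 0, 0)]
        b = [feat(FeatureKind.HAC, 0.3, 0, 0), feat(FeatureKind.ARO, 5, 0, 0)]
        model = consensus_features([a, b], min_support=1.0, merge_radius=1.0)
        hac = [f for f in model.features if f.kind is FeatureKind.HAC]
        assert len(hac) == 1
        assert hac[0].center[0] == pytest.approx(0.15)

    def test_fewer_than_two_actives_rejected(self):
        with pytest.raises(ValueError):
            consensus_features([[feat(FeatureKind.HAC, 0, 0, 0)]], min_support=1.0)

    def test_published_model_composition_from_entered_features(self):
        # the five-feature VEGFR-2-style map: 2 HAC + 2 HPB + 1 ARO
        feats = [
            feat(FeatureKind.HAC, 0, 0, 0),
            feat(FeatureKind.HAC, 4, 1, 0),
            feat(FeatureKind.HPB, 2, -2, 1),
            feat(FeatureKind.HPB, 6, -1, 0),
            feat(FeatureKind.ARO, 3, 2, -1),
        ]
        model = PharmacophoreModel(name="vegfr2", features=feats)
        assert model.kind_counts() == {"HAC": 2, "HPB": 2, "ARO": 1}


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path):
        model = PharmacophoreModel(
            name="m",
            features=[feat(FeatureKind.HAC, 0, 0, 0), feat(FeatureKind.ARO, 3, 0, 0)],
        )
        dest = tmp_path / "model.json"
        model.to_json(dest)
        back = PharmacophoreModel.from_json(dest)
        assert back.name == model.name and back.features == model.features
        assert back.required_count == model.required_count

    def test_single_feature_model_rejected(self):
        with pytest.raises(ValueError):
            PharmacophoreModel(name="m", features=[feat(FeatureKind.HAC, 0, 0, 0)])
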