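import numpy as np
import pytest
from rdkit import Chem

from consensus_vs import chem_core, fixtures, pharmacophore
from consensus_vs.chem_core import Molecule
from consensus_vs.errors import ContractViolationError
from conftest import random_rotation


def mol_with_coords(smiles, coords):
    mol = Chem.MolFromSmiles(smiles)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, p in enumerate(coords):
        conf.SetAtomPosition(i, tuple(float(x) for x in p))
    mol.AddConformer(conf)
    return Molecule(id=smiles, rdmol=mol)


def planar_benzene(center=(0.0, 0.0, 0.0)):
    angles = np.arange(6) * np.pi / 3
    pts = np.asarray(center) + 1.39 * np.stack(
        [np.cos(angles), np.sin(angles), np.zeros(6)], axis=1
    )
    return mol_with_coords("c1ccccc1", pts)


class TestPerceiveFeatures:
    def test_benzene_single_aromatic_at_centroid(self):
        pose = planar_benzene((1.0, 2.0, 3.0))
        feats = pharmacophore.perceive_features(pose)
        assert len(feats) == 1
        ftype, point = feats[0]
        assert ftype == "aromatic"
        assert np.allclose(point, (1.0, 2.0, 3.0), atol=1e-6)

    def test_methanol_donor_and_acceptor_at_oxygen(self):
        pose = mol_with_coords("CO", [(0.0, 0.0, 0.0), (1.43, 0.0, 0.0)])
        feats = pharmacophore.perceive_features(pose)
        types = sorted(f for f, _ in feats)
        assert types == ["acceptor", "donor"]
        for _, point in feats:
            assert np.allclose(point, (1.43, 0.0, 0.0))

    def test_hexane_single_hydrophobic_at_carbon_centroid(self):
        pts = [(float(i) * 1.3, 0.0, 0.0) for i in range(6)]
        pose = mol_with_coords("CCCCCC", pts)
        feats = pharmacophore.perceive_features(pose)
        assert [f for f, _ in feats] == ["hydrophobic"]
        assert np.allclose(feats[0][1], np.mean(pts, axis=0))

    def test_missing_coordinates_raises(self, benzene):
        with pytest.raises(ContractViolationError):
            pharmacophore.perceive_features(benzene)

    def test_heteroatom_bonded_carbons_not_hydrophobic(self):
        # ethylene glycol dimethyl ether: every carbon touches an oxygen
        pose = mol_with_coords(
            "COCCOC", [(i * 1.4, 0.0, 0.0) for i in range(6)]
        )
        feats = pharmacophore.perceive_features(pose)
        assert "hydrophobic" not in {f for f, _ in feats}


class TestMinReferenceCount:
    def test_seventy_percent_of_twenty(self):
        assert pharmacophore.min_reference_count(20, 0.70) == 14

    def test_seventy_percent_of_ten(self):
        assert pharmacophore.min_reference_count(10, 0.70) == 7

    def test_full_prevalence(self):
        assert pharmacophore.min_reference_count(20, 1.0) == 20

    @pytest.mark.parametrize("n,thr,expected", [(1, 0.5, 1), (3, 0.34, 2), (7, 0.7, 5)])
    def test_ceiling(self, n, thr, expected):
        assert pharmacophore.min_reference_count(n, thr) == expected


class TestBuildPharmacophore:
    def test_identical_copies_full_prevalence(self):
        poses, _ = fixtures.generate_pose_set(
            [(f, p, 1.0) for f, p, _ in fixtures.default_planted_features()],
            n_poses=10,
            seed=0,
        )
        model = pharmacophore.build_pharmacophore(poses)
        assert len(model.features) == 6
        assert all(f.prevalence == 1.0 for f in model.features)

    def test_thirteen_of_twenty_excluded(self):
        planted = [
            ("donor", (0.0, 0.0, 0.0), 0.90),
            ("acceptor", (8.0, 0.0, 0.0), 13 / 20),  # below the 14-of-20 minimum
        ]
        poses, _ = fixtures.generate_pose_set(planted, n_poses=20, seed=1)
        model = pharmacophore.build_pharmacophore(poses, prevalence_threshold=0.70)
        assert [f.ftype for f in model.features] == ["donor"]

    def test_scripted_prevalences(self):
        planted = [
            ("donor", (0.0, 0.0, 0.0), 0.9),
            ("aromatic", (9.0, 0.0, 0.0), 0.75),
            ("hydrophobic", (0.0, 9.0, 0.0), 0.5),
        ]
        poses, _ = fixtures.generate_pose_set(planted, n_poses=20, seed=2)
        model = pharmacophore.build_pharmacophore(poses)
        kept = {f.ftype for f in model.features}
        assert kept == {"donor", "aromatic"}

    def test_pose_order_invariant(self, rng):
        poses, _ = fixtures.generate_pose_set(
            fixtures.default_planted_features(), 12, seed=3
        )
        a = pharmacophore.build_pharmacophore(poses)
        shuffled = [poses[i] for i in rng.permutation(len(poses))]
        b = pharmacophore.build_pharmacophore(shuffled)
        assert {
            (f.ftype, tuple(round(c, 6) for c in f.centroid), round(f.prevalence, 9))
            for f in a.features
        } == {
            (f.ftype, tuple(round(c, 6) for c in f.centroid), round(f.prevalence, 9))
            for f in b.features
        }

    def test_feature_count_nonincreasing_in_threshold(self):
        poses, _ = fixtures.generate_pose_set(
            fixtures.default_planted_features(), 20, seed=4
        )
        counts = [
            len(pharmacophore.build_pharmacophore(poses, prevalence_threshold=t).features)
            for t in (0.5, 0.7, 0.8, 0.95)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_too_few_poses_raises(self):
        poses, _ = fixtures.generate_pose_set(
            fixtures.default_planted_features(), 5, seed=0
        )
        with pytest.raises(ContractViolationError):
            pharmacophore.build_pharmacophore(poses[:1])

    def test_planted_recovery_within_merge_radius(self):
        planted = fixtures.default_planted_features()
        poses, _ = fixtures.generate_pose_set(planted, 20, seed=5)
        model = pharmacophore.build_pharmacophore(poses)
        assert len(model.features) == len(planted)
        for ftype, point, _ in planted:
            dists = [
                np.linalg.norm(np.asarray(f.centroid) - np.asarray(point))
                for f in model.features
                if f.ftype == ftype
            ]
            assert min(dists) <= pharmacophore.DEFAULT_MERGE_RADIUS


class TestMatchPharmacophore:
    @pytest.fixture
    def model(self):
        poses, _ = fixtures.generate_pose_set(
            fixtures.default_planted_features(), 20, seed=6
        )
        return pharmacophore.build_pharmacophore(poses)

    def pose_with(self, k, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        feats = [
            (f, np.asarray(p)) for f, p, _ in fixtures.default_planted_features()[:k]
        ]
        return fixtures._assemble_pose(feats, rng, pose_id=f"k{k}")

    def test_all_six_pass(self, model):
        assert pharmacophore.match_pharmacophore(self.pose_with(6), model) == (6, True)

    def test_five_of_six_pass(self, model):
        assert pharmacophore.match_pharmacophore(self.pose_with(5), model) == (5, True)

    def test_four_of_six_fail(self, model):
        assert pharmacophore.match_pharmacophore(self.pose_with(4), model) == (4, False)

    def test_greedy_and_optimal_agree_on_planted(self, model):
        for k in range(0, 7):
            pose = self.pose_with(k, rng_seed=k)
            greedy = pharmacophore.match_pharmacophore(pose, model)
            optimal = pharmacophore.match_pharmacophore(pose, model, optimal=True)
            assert greedy == optimal

    def test_rigid_transform_invariance(self, model, rng):
        pose = self.pose_with(6)
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, size=3)

        moved_pose_mol = Chem.Mol(pose.rdmol)
        conf = moved_pose_mol.GetConformer()
        for i in range(moved_pose_mol.GetNumAtoms()):
            p = np.array(conf.GetAtomPosition(i))
            conf.SetAtomPosition(i, tuple(R @ p + t))
        moved_pose = Molecule(id="moved", rdmol=moved_pose_mol)

        moved_model = pharmacophore.PharmacophoreModel(
            features=tuple(
                pharmacophore.PharmacophoreFeature(
                    f.ftype, tuple(R @ np.asarray(f.centroid) + t), f.tolerance, f.prevalence
                )
                for f in model.features
            ),
            n_references=model.n_references,
            prevalence_threshold=model.prevalence_threshold,
            min_match=model.min_match,
        )
        assert pharmacophore.match_pharmacophore(
            moved_pose, moved_model
        ) == pharmacophore.match_pharmacophore(pose, model)


class TestModelSerialization:
    def test_json_roundtrip(self, tmp_path):
        poses, _ = fixtures.generate_pose_set(
            fixtures.default_planted_features(), 12, seed=7
        )
        model = pharmacophore.build_pharmacophore(poses)
        path = tmp_path / "model.json"
        pharmacophore.save_model(model, path)
        back = pharmacophore.load_model(path)
        assert back == model
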