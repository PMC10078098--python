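import numpy as np
import pytest

from consensus_vs import chem_core, docking_post, fixtures
from consensus_vs.docking_post import (
    COLCHICINE_SMILES,
    ComplexStructure,
    ContactProfile,
    DockingRecord,
    ProteinAtom,
)
from consensus_vs.errors import ContractViolationError, FormatError
from conftest import random_rotation


class TestNormalizeScore:
    def test_reference_worked_example(self, colchicine):
        n = chem_core.heavy_atom_count(colchicine)
        assert n == 29
        assert docking_post.normalized_score_rounded(-10.01, n) == -0.345

    def test_zero_score(self):
        for k in (1, 7, 100):
            assert docking_post.normalize_score(0.0, k) == 0.0

    def test_simple_ratio(self):
        assert docking_post.normalize_score(-10.0, 10) == -1.0

    def test_invalid_heavy_count(self):
        with pytest.raises(ContractViolationError):
            docking_post.normalize_score(-5.0, 0)

    def test_strictly_monotone_in_raw(self):
        scores = sorted(np.random.default_rng(0).uniform(-20, 0, size=50))
        normalized = [docking_post.normalize_score(s, 13) for s in scores]
        assert all(b > a for a, b in zip(normalized, normalized[1:]))


class TestScoreTable:
    def write_table(self, tmp_path, rows):
        path = tmp_path / "scores.csv"
        path.write_text("compound_id,raw_score\n" + "\n".join(rows) + "\n")
        return path

    def test_all_known_ids(self, tmp_path, small_library):
        rows = [f"{m.id},-{5 + i}" for i, m in enumerate(small_library[:5])]
        records = docking_post.read_score_table(
            self.write_table(tmp_path, rows), small_library
        )
        assert len(records) == 5

    def test_unknown_id_excluded(self, tmp_path, small_library, caplog):
        rows = [f"{m.id},-5" for m in small_library[:4]] + ["GHOST,-9"]
        records = docking_post.read_score_table(
            self.write_table(tmp_path, rows), small_library
        )
        assert len(records) == 4
        assert "GHOST" in caplog.text

    def test_duplicate_keeps_best(self, tmp_path, small_library):
        cid = small_library[0].id
        rows = [f"{cid},-5.0", f"{cid},-8.0", f"{cid},-6.0"]
        records = docking_post.read_score_table(
            self.write_table(tmp_path, rows), small_library
        )
        assert len(records) == 1
        assert records[0].raw_score == -8.0

    def test_missing_column(self, tmp_path, small_library):
        path = tmp_path / "bad.csv"
        path.write_text("compound_id,score\nA,-5\n")
        with pytest.raises(FormatError):
            docking_post.read_score_table(path, small_library)


class TestDockingHits:
    reference = DockingRecord("ref", -10.01, 29)

    def test_equal_to_cutoff_is_hit(self):
        cutoff = self.reference.normalized_score
        rec = DockingRecord("x", cutoff * 20, 20)
        assert docking_post.docking_hits([rec], self.reference) == {"x"}

    def test_above_cutoff_not_hit(self):
        rec = DockingRecord("x", -0.344 * 20, 20)
        assert docking_post.docking_hits([rec], self.reference) == set()

    def test_matches_bruteforce_filter(self, rng):
        records = [
            DockingRecord(f"C{i}", float(rng.uniform(-15, -2)), int(rng.integers(8, 40)))
            for i in range(100)
        ]
        hits = docking_post.docking_hits(records, self.reference)
        cutoff = -10.01 / 29
        brute = {r.compound_id for r in records if r.raw_score / r.n_heavy <= cutoff}
        assert hits == brute

    def test_permutation_invariant(self, rng):
        records = [
            DockingRecord(f"C{i}", float(rng.uniform(-15, -2)), int(rng.integers(8, 40)))
            for i in range(50)
        ]
        hits = docking_post.docking_hits(records, self.reference)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        assert docking_post.docking_hits(shuffled, self.reference) == hits


def toy_complex(residue_distances):
    """One CA per residue at the given distance from a 1-atom ligand at origin."""
    dirs = fixtures._unit_directions(max(len(residue_distances), 2))
    protein = tuple(
        ProteinAtom("C", tuple(dirs[k] * d), "A", name.upper(), num)
        for k, ((name, num), d) in enumerate(residue_distances.items())
    )
    return ComplexStructure(protein, (("C", (0.0, 0.0, 0.0)),), 0)


class TestDetectContacts:
    def test_below_cutoff(self):
        c = toy_complex({("Val", 181): 4.4})
        assert docking_post.detect_contacts(c) == {"Val 181"}

    def test_above_cutoff(self):
        c = toy_complex({("Val", 181): 4.6})
        assert docking_post.detect_contacts(c) == set()

    def test_boundary_inclusive_vs_oracle(self):
        c = toy_complex({("Ala", 180): 3.0, ("Val", 181): 4.5, ("Met", 259): 6.0})
        contacts = docking_post.detect_contacts(c, 4.5)
        # brute-force all-pairs distances
        brute = set()
        for atom in c.protein_atoms:
            for _, lig in c.ligand_atoms:
                d = np.linalg.norm(np.array(atom.coord) - np.array(lig))
                if d <= 4.5:
                    brute.add(atom.residue_id)
        assert contacts == brute == {"Ala 180", "Val 181"}

    def test_empty_ligand_raises(self):
        c = ComplexStructure(toy_complex({("Val", 181): 3.0}).protein_atoms, (), 0)
        with pytest.raises(ContractViolationError):
            docking_post.detect_contacts(c)

    def test_rigid_transform_invariance(self, rng):
        c = toy_complex({("Ala", 180): 3.0, ("Val", 181): 5.0, ("Met", 259): 4.2})
        base = docking_post.detect_contacts(c)
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, size=3)

        def move(p):
            return tuple(R @ np.asarray(p) + t)

        moved = ComplexStructure(
            tuple(
                ProteinAtom(a.element, move(a.coord), a.chain, a.residue_name, a.residue_number)
                for a in c.protein_atoms
            ),
            tuple((el, move(p)) for el, p in c.ligand_atoms),
            0,
        )
        assert docking_post.detect_contacts(moved) == base


class TestContactPersistence:
    def test_three_of_four_frames(self, tmp_path):
        path = tmp_path / "traj.pdb"
        fixtures.generate_toy_complex(
            {"Val 181": [3.0, 3.0, 3.0, 8.0], "Met 259": 3.5}, n_frames=4, path=path
        )
        frames = docking_post.read_complex_pdb(path)
        profile = docking_post.contact_persistence(frames)
        assert profile.contacts["Val 181"] == pytest.approx(0.75)
        assert profile.contacts["Met 259"] == pytest.approx(1.0)

    def test_single_frame_binary(self, tmp_path):
        path = tmp_path / "one.pdb"
        fixtures.generate_toy_complex({"Val 181": 3.0, "Ala 316": 9.0}, 1, path)
        profile = docking_post.contact_persistence(
            docking_post.read_complex_pdb(path)
        )
        assert set(profile.contacts.values()) <= {0.0, 1.0}

    def test_constant_trajectory_equals_single_frame(self, tmp_path):
        plan = {"Ala 180": 2.5, "Cys 241": 4.0, "Met 259": 7.7}
        p1, p4 = tmp_path / "f1.pdb", tmp_path / "f4.pdb"
        fixtures.generate_toy_complex(plan, 1, p1)
        fixtures.generate_toy_complex(plan, 4, p4)
        single = docking_post.detect_contacts(docking_post.read_complex_pdb(p1)[0])
        profile = docking_post.contact_persistence(docking_post.read_complex_pdb(p4))
        assert set(profile.contacts) == single
        assert all(v == 1.0 for v in profile.contacts.values())

    def test_scripted_pattern_recovered(self, tmp_path, rng):
        n_frames = 6
        plan = {}
        expected = {}
        for name, num in [("Ala", 180), ("Val", 181), ("Cys", 241), ("Met", 259)]:
            pattern = rng.integers(0, 2, size=n_frames)
            plan[f"{name} {num}"] = [3.0 if c else 8.0 for c in pattern]
            expected[f"{name} {num}"] = pattern.sum() / n_frames
        path = tmp_path / "scripted.pdb"
        fixtures.generate_toy_complex(plan, n_frames, path)
        profile = docking_post.contact_persistence(docking_post.read_complex_pdb(path))
        for rid, frac in expected.items():
            assert profile.contacts.get(rid, 0.0) == pytest.approx(frac)


class TestKeyInteractionCheck:
    def make_profile(self, residues):
        return ContactProfile("x", {r: 1.0 for r in residues}, 1)

    def test_three_matches_pass(self):
        profile = self.make_profile(["Ala 180", "Val 181", "Cys 241"])
        assert docking_post.key_interaction_check(
            profile, docking_post.KEY_RESIDUES["colchicine"]
        ) == (3, True)

    def test_one_match_fails(self):
        profile = self.make_profile(["Val 181"])
        assert docking_post.key_interaction_check(
            profile, docking_post.KEY_RESIDUES["colchicine"]
        ) == (1, False)

    def test_empty_profile(self):
        profile = ContactProfile("x", {}, 1)
        assert docking_post.key_interaction_check(
            profile, docking_post.KEY_RESIDUES["dj101"]
        ) == (0, False)

    def test_empty_key_set_raises(self):
        with pytest.raises(ContractViolationError):
            docking_post.key_interaction_check(ContactProfile("x", {}, 1), [])
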