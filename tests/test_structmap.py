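"""N-H vector extraction, C2 alignment, and B-factor value maps."""

import gemmi
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from amidyn import structmap, synth
from amidyn.structmap import (
    ResidueValueMap,
    align_c2,
    construct_amide_H,
    nh_vectors,
    write_value_map,
)

PDB_TWO_RESIDUES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.420   0.000  1.00  0.00           C
ATOM      4  N   ALA A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      5  H   ALA A   2       3.800   0.700   0.300  1.00  0.00           H
ATOM      6  CA  ALA A   2       4.100   2.700   0.000  1.00  0.00           C
END
"""


@pytest.fixture()
def two_residue_structure(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(PDB_TWO_RESIDUES)
    return structmap.read_structure(p)


class TestNhVectors:
    def test_explicit_h_vector_matches_hand_computation(self, two_residue_structure):
        frame = nh_vectors(two_residue_structure)
        n = np.array([3.3, 1.5, 0.0])
        h = np.array([3.8, 0.7, 0.3])
        expect = (h - n) / np.linalg.norm(h - n)
        np.testing.assert_allclose(frame.nh_vectors["A:2"], expect, atol=1e-12)

    def test_chain_start_reported_not_fabricated(self, two_residue_structure):
        frame = nh_vectors(two_residue_structure)
        assert "A:1" in frame.skipped
        assert "chain start" in frame.skipped["A:1"]

    def test_all_vectors_unit_norm(self, toy_dimer):
        frame = nh_vectors(toy_dimer)
        for v in frame.nh_vectors.values():
            assert abs(np.linalg.norm(v) - 1.0) < 1e-9

    def test_constructed_h_reproduces_explicit_h_direction(self, toy_dimer, tmp_path):
        # write, strip explicit H, re-derive; direction within 5 degrees
        path = tmp_path / "dimer.pdb"
        toy_dimer.write_pdb(str(path))
        st = structmap.read_structure(path)
        ref = nh_vectors(structmap.read_structure(path)).nh_vectors
        for chain in st[0]:
            for res in chain:
                for i in reversed(range(len(res))):
                    if res[i].name == "H":
                        del res[i]
        rebuilt = nh_vectors(st).nh_vectors
        assert set(rebuilt) == set(ref)
        for rid, v in rebuilt.items():
            cosang = np.clip(np.dot(v, ref[rid]), -1, 1)
            assert np.degrees(np.arccos(cosang)) < 5.0

    def test_deterministic_under_atom_reordering(self, tmp_path):
        lines = PDB_TWO_RESIDUES.splitlines()
        reordered = "\n".join([lines[0], lines[2], lines[1], lines[4], lines[3],
                               lines[5], "END"]) + "\n"
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        p1.write_text(PDB_TWO_RESIDUES)
        p2.write_text(reordered)
        f1 = nh_vectors(structmap.read_structure(p1)).nh_vectors
        f2 = nh_vectors(structmap.read_structure(p2)).nh_vectors
        np.testing.assert_allclose(f1["A:2"], f2["A:2"], atol=1e-12)

    def test_proline_skipped(self, tmp_path):
        text = PDB_TWO_RESIDUES.replace("ALA A   2", "PRO A   2")
        p = tmp_path / "pro.pdb"
        p.write_text(text)
        frame = nh_vectors(structmap.read_structure(p))
        assert "proline" in frame.skipped["A:2"]

    def test_constructed_h_bond_length(self):
        N = np.array([0.0, 0.0, 0.0])
        CA = np.array([1.458, 0.0, 0.0])
        C_prev = np.array([-0.7, 1.1, 0.0])
        H = construct_amide_H(N, CA, C_prev)
        assert np.linalg.norm(H - N) == pytest.approx(1.02)


def _all_coords(st):
    out = []
    for chain in st[0]:
        for res in chain:
            for atom in res:
                out.append(atom.pos.tolist())
    return np.array(out)


class TestAlignC2:
    def test_already_aligned_dimer_gets_identity_transform(self, toy_dimer):
        st = synth.make_toy_dimer(12)
        before = _all_coords(st)
        rep = align_c2(st)
        after = _all_coords(st)
        assert rep.angle_deg == pytest.approx(180.0, abs=1e-6)
        np.testing.assert_allclose(rep.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(after, before, atol=1e-9)

    def test_planted_rotation_recovered_within_tenth_degree(self):
        st = synth.make_toy_dimer(12)
        R = Rotation.from_rotvec([0.4, -0.7, 0.2]).as_matrix()
        shift = np.array([5.0, -3.0, 2.0])
        for chain in st[0]:
            for res in chain:
                for atom in res:
                    p = np.array(atom.pos.tolist())
                    atom.pos = gemmi.Position(*(R @ p + shift))
        align_c2(st)
        rep = align_c2(st)  # re-derive the axis after alignment
        axis_dev = np.degrees(np.arccos(np.clip(abs(rep.axis[2]), -1, 1)))
        assert axis_dev < 0.1

    def test_chain_swap_gives_same_axis_line(self):
        st1 = synth.make_toy_dimer(10)
        st2 = synth.make_toy_dimer(10)
        r1 = align_c2(st1, ("A", "B"))
        r2 = align_c2(st2, ("B", "A"))
        assert abs(np.dot(r1.axis, r2.axis)) == pytest.approx(1.0, abs=1e-9)
        assert r1.axis[2] >= 0 and r2.axis[2] >= 0  # canonical representative

    def test_alignment_is_an_isometry(self):
        st = synth.make_toy_dimer(8)
        R = Rotation.from_rotvec([0.1, 0.2, 0.3]).as_matrix()
        for chain in st[0]:
            for res in chain:
                for atom in res:
                    p = np.array(atom.pos.tolist())
                    atom.pos = gemmi.Position(*(R @ p))
        before = _all_coords(st)
        d_before = np.linalg.norm(before[:, None] - before[None, :], axis=-1)
        align_c2(st)
        after = _all_coords(st)
        d_after = np.linalg.norm(after[:, None] - after[None, :], axis=-1)
        np.testing.assert_allclose(d_after, d_before, atol=1e-9)

    def test_non_c2_pair_refused_but_overridable(self):
        st = synth.make_toy_dimer(10)
        Rz30 = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        for chain in st[0]:
            if chain.name != "B":
                continue
            for res in chain:
                for atom in res:
                    p = np.array(atom.pos.tolist())
                    atom.pos = gemmi.Position(*(Rz30 @ p))
        with pytest.raises(ValueError, match="not C2-symmetric"):
            align_c2(st)
        align_c2(st, force=True)  # must not raise


class TestValueMap:
    def test_round_trip_preserves_coordinates(self, tmp_path):
        st = synth.make_toy_dimer(6)
        before = _all_coords(st)
        out = tmp_path / "map.pdb"
        write_value_map(st, ResidueValueMap("S2", {"A:2": 0.9}), out)
        st2 = structmap.read_structure(out)
        after = _all_coords(st2)
        np.testing.assert_allclose(after, before, atol=1e-3)  # file precision

    def test_stated_scaling_rule(self, tmp_path):
        st = synth.make_toy_dimer(4)
        vm = ResidueValueMap("CSP", {"A:1": 0.0, "A:2": 50.0, "A:3": 100.0})
        table = write_value_map(st, vm, tmp_path / "m.pdb", tmp_path / "m.tsv")
        scaled = table.set_index("residue_id")["scaled"]
        assert scaled["A:1"] == 0.0
        assert scaled["A:2"] == pytest.approx(50.0, abs=0.01)
        assert scaled["A:3"] == pytest.approx(99.99)
        assert np.isnan(scaled["A:4"])  # unmapped residue listed

    def test_constant_map_gives_constant_column(self, tmp_path):
        st = synth.make_toy_dimer(4)
        vm = ResidueValueMap("Rex", {f"A:{i}": 3.0 for i in range(1, 5)})
        write_value_map(st, vm, tmp_path / "m.pdb")
        bs = {a.b_iso for ch in st[0] for r in ch for a in r if ch.name == "A"}
        assert len(bs) == 1

    def test_missing_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            ResidueValueMap("", {"A:1": 1.0})

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ResidueValueMap("S2", {"A:1": np.nan})


class TestAltloc:
    def test_highest_occupancy_conformer_wins(self, tmp_path):
        text = (
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.30  0.00           N\n"
            "ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.70  0.00           N\n"
            "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        st = structmap.read_structure(p)
        atoms = structmap._residue_atoms(st[0]["A"][0])
        np.testing.assert_allclose(atoms["N"], [9.0, 0.0, 0.0])
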