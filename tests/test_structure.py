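"""Superposition RMSD, buried interface area, domain rotations."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from trpckit import structure as st
from trpckit import synthetic as syn


PDB_3ATOM = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       3.800   3.800   0.000  1.00  0.00           C
END
"""

CIF_3ATOM = """\
data_fixture
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C CA . ALA A A 1 ? 0.000 0.000 0.000 1.00 0.00 1 A 1
ATOM 2 C CA . ALA A A 2 ? 3.800 0.000 0.000 1.00 0.00 2 A 1
ATOM 3 C CA . ALA A A 3 ? 3.800 3.800 0.000 1.00 0.00 3 A 1
"""


class TestReadStructure:
    def test_pdb_fixture(self, tmp_path):
        p = tmp_path / "fix.pdb"
        p.write_text(PDB_3ATOM)
        model = st.read_structure(p)
        assert len(model) == 3
        assert model.coord[1] == pytest.approx([3.8, 0.0, 0.0])
        assert (model.element == "C").all()
        assert model.radius == pytest.approx([1.7] * 3)

    def test_cif_and_pdb_agree(self, tmp_path):
        pp = tmp_path / "fix.pdb"
        pc = tmp_path / "fix.cif"
        pp.write_text(PDB_3ATOM)
        pc.write_text(CIF_3ATOM)
        a = st.read_structure(pp)
        b = st.read_structure(pc)
        assert np.allclose(a.coord, b.coord)
        assert (a.atom_name == b.atom_name).all()

    def test_missing_element_inferred(self, tmp_path):
        p = tmp_path / "noel.pdb"
        p.write_text(PDB_3ATOM.replace("           C", "            "))
        model = st.read_structure(p)
        assert (model.element == "C").all()
        assert model.radius == pytest.approx([1.7] * 3)


class TestSuperpose:
    def test_identical_models_zero_rmsd(self):
        a, b, _ = syn.gen_structure_fixture("rotated-copy", angle_deg=0.0)
        res = st.superpose(a, b)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_known_transform_recovered_under_noise(self):
        a, b, R_true = syn.gen_structure_fixture(
            "rotated-copy", n_atoms=100, angle_deg=30.0,
            translation=(5.0, -3.0, 2.0), noise_sd=0.1, seed=8)
        res = st.superpose(a, b)
        # residual at the coordinate-noise level, rotation near truth
        assert res.rmsd == pytest.approx(0.1 * np.sqrt(3), rel=0.3)
        angle_err = np.degrees(Rotation.from_matrix(
            res.rotation @ R_true.T).magnitude())
        assert angle_err < 1.0

    def test_rmsd_symmetry(self, gating_model):
        a, b, _ = syn.gen_structure_fixture("rotated-copy", angle_deg=25.0,
                                            noise_sd=0.2, seed=3)
        r1 = st.superpose(a, b).rmsd
        r2 = st.superpose(b, a).rmsd
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_invariance_under_rigid_pretransform(self):
        a, b, _ = syn.gen_structure_fixture("rotated-copy", angle_deg=25.0,
                                            noise_sd=0.2, seed=3)
        R = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        a_moved = a.transformed(R, np.array([10.0, -5.0, 3.0]))
        assert st.superpose(a_moved, b).rmsd == pytest.approx(
            st.superpose(a, b).rmsd, abs=1e-9)

    def test_collinear_points_error(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        m = syn._as_model(coords)
        with pytest.raises(ValueError, match="collinear"):
            st.superpose(m, m)

    def test_too_few_pairs_error(self):
        a = syn._as_model(np.eye(3) * 5)
        two = a.subset(np.array([True, True, False]))
        with pytest.raises(ValueError, match="3 paired atoms"):
            st.superpose(two, two)


class TestBuriedInterfaceArea:
    GA = st.Selection(chains=frozenset({"A"}))
    GB = st.Selection(chains=frozenset({"B"}))

    def test_separated_groups_bury_nothing(self):
        m = syn.gen_structure_fixture("two-body-complex", separation=20.0,
                                      radius=2.0)
        out = st.buried_interface_area(m, self.GA, self.GB)
        assert out["buried_per_side_A2"] == 0.0

    def test_matches_sphere_cap_oracle(self):
        # two equal spheres: the probe-inflated radius is R = r + probe
        # and each loses a cap of area 2*pi*R*(R - d/2)
        r, probe, d = 2.0, 1.4, 3.0
        m = syn.gen_structure_fixture("two-body-complex", separation=d,
                                      radius=r)
        out = st.buried_interface_area(m, self.GA, self.GB, probe=probe,
                                       n_points=960)
        R = r + probe
        cap = 2 * np.pi * R * (R - d / 2)
        assert out["buried_per_side_A2"] == pytest.approx(cap, rel=0.02)

    def test_symmetric_in_groups(self):
        m = syn.gen_structure_fixture("two-body-complex", separation=3.0)
        ab = st.buried_interface_area(m, self.GA, self.GB)
        ba = st.buried_interface_area(m, self.GB, self.GA)
        assert ab["buried_per_side_A2"] == pytest.approx(
            ba["buried_per_side_A2"], rel=1e-9)

    def test_monotone_under_separation(self):
        areas = []
        for d in (2.0, 3.0, 4.0, 5.0, 6.0, 8.0):
            m = syn.gen_structure_fixture("two-body-complex", separation=d)
            areas.append(st.buried_interface_area(
                m, self.GA, self.GB)["buried_per_side_A2"])
        assert all(a >= b - 1e-9 for a, b in zip(areas, areas[1:]))

    def test_overlapping_groups_error(self):
        m = syn.gen_structure_fixture("two-body-complex", separation=3.0)
        both = np.ones(len(m), bool)
        with pytest.raises(ValueError, match="overlap"):
            st.buried_interface_area(m, both, both)

    def test_sasa_point_convergence(self):
        m, _, _ = syn.gen_structure_fixture("rotated-copy", n_atoms=40, seed=5)
        a1 = st.sasa(m, n_points=960)
        a2 = st.sasa(m, n_points=1920)
        assert abs(a1 - a2) / a2 < 0.005


class TestDomainRotation:
    FRAME = st.Selection(chains=frozenset({"F"}))
    DOMAIN = st.Selection(chains=frozenset({"D"}))
    Z = np.array([0.0, 0.0, 1.0])

    def test_identical_models_zero_angle(self):
        a, b = syn.gen_structure_fixture("frame-domain", angle_deg=0.0, seed=1)
        dm = st.domain_rotation(a, b, self.FRAME, self.DOMAIN, axis=self.Z)
        assert dm.angle_deg == pytest.approx(0.0, abs=1e-6)

    def test_45_degree_screw_motion_recovered(self):
        # the conformational change reported for the coiled-coil domain:
        # 45 degree twist about the four-fold axis with a 5 A descent
        a, b = syn.gen_structure_fixture("frame-domain", angle_deg=45.0,
                                         translation=(0.0, 0.0, -5.0), seed=2)
        dm = st.domain_rotation(a, b, self.FRAME, self.DOMAIN, axis=self.Z)
        assert dm.angle_deg == pytest.approx(45.0, abs=0.1)
        assert dm.translation_along_axis == pytest.approx(-5.0, abs=0.01)
        assert dm.frame_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_8_degree_rotation_recovered(self):
        a, b = syn.gen_structure_fixture("frame-domain", angle_deg=8.0, seed=3)
        dm = st.domain_rotation(a, b, self.FRAME, self.DOMAIN, axis=self.Z)
        assert dm.angle_deg == pytest.approx(8.0, abs=0.1)


class TestRoundTripPdbWrite:
    def test_model_survives_pdb_io(self, tmp_path):
        a, _, _ = syn.gen_structure_fixture("rotated-copy", n_atoms=10, seed=6)
        p = tmp_path / "blob.pdb"
        a.write_pdb(p)
        back = st.read_structure(p)
        assert len(back) == 10
        assert np.allclose(back.coord, a.coord, atol=1e-2)  # PDB precision
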