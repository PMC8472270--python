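"""PDB handling, Kabsch superposition, oligomer templating, Kirkwood R_S."""

import math

import numpy as np
import pytest

import pepassoc as pa
from pepassoc.constants import AVOGADRO
from pepassoc.structure import OligomerResult, transform

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.560   6.351  -6.508  1.00  0.00           C
ATOM      3  C   ALA A   1      13.276   5.261  -5.709  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   3       3.800   3.800   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   3       4.800   3.800   0.000  1.00  0.00           C
ENDMDL
END
"""


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestReadStructure:
    def test_minimal_fixture_round_trip(self):
        atoms = pa.read_structure(THREE_ATOM_PDB)
        assert len(atoms) == 3
        np.testing.assert_allclose(atoms.coords[1], [12.560, 6.351, -6.508])
        assert list(atoms.atom_names) == ["N", "CA", "C"]

    def test_model_selection(self):
        m1 = pa.read_structure(TWO_MODEL_PDB, model_index=1)
        m2 = pa.read_structure(TWO_MODEL_PDB, model_index=2)
        assert m1.coords[0, 0] == 0.0
        assert m2.coords[0, 0] == 1.0

    def test_missing_model_lists_available(self):
        with pytest.raises(ValueError, match="1..2"):
            pa.read_structure(TWO_MODEL_PDB, model_index=5)

    def test_garbage_coordinates_name_line(self):
        bad = THREE_ATOM_PDB.replace("12.560", "twelve")
        with pytest.raises(ValueError, match="line 2"):
            pa.read_structure(bad)

    def test_ca_only(self):
        atoms = pa.read_structure(THREE_ATOM_PDB, ca_only=True)
        assert len(atoms) == 1
        assert atoms.atom_names[0] == "CA"

    def test_write_read_round_trip(self, tmp_path):
        atoms = pa.read_structure(THREE_ATOM_PDB)
        out = tmp_path / "out.pdb"
        pa.write_pdb(atoms, out)
        back = pa.read_structure(out)
        np.testing.assert_allclose(back.coords, atoms.coords, atol=1e-3)


class TestKabsch:
    def test_identical_sets(self):
        x = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.2, 1.5]])
        res = pa.kabsch_superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_constructed_rotation_recovered(self, rng):
        x = rng.normal(size=(6, 3))
        rot90 = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        y = x @ rot90.T + np.array([1.0, -2.0, 3.0])
        res = pa.kabsch_superpose(x, y)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, rot90, atol=1e-9)

    def test_always_proper_rotation(self, rng):
        for _ in range(20):
            x = rng.normal(size=(5, 3))
            y = rng.normal(size=(5, 3))
            res = pa.kabsch_superpose(x, y)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_symmetric_in_arguments(self, rng):
        x = rng.normal(size=(7, 3))
        y = x @ random_rotation(rng).T + rng.normal(size=(7, 3)) * 0.3
        assert pa.kabsch_superpose(x, y).rmsd == pytest.approx(
            pa.kabsch_superpose(y, x).rmsd, rel=1e-9
        )

    def test_invariant_under_joint_rigid_motion(self, rng):
        x = rng.normal(size=(6, 3))
        y = x + rng.normal(size=(6, 3)) * 0.2
        base = pa.kabsch_superpose(x, y).rmsd
        rot = random_rotation(rng)
        shift = np.array([4.0, -1.0, 2.0])
        moved = pa.kabsch_superpose(x @ rot.T + shift, y @ rot.T + shift).rmsd
        assert moved == pytest.approx(base, rel=1e-9)

    def test_collinear_pairing_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            pa.kabsch_superpose(line, line + 1.0)

    def test_agrees_with_biotite_superimpose(self, rng):
        import biotite.structure as struc

        x = rng.normal(size=(10, 3))
        y = x @ random_rotation(rng).T + rng.normal(size=(10, 3)) * 0.4 + 2.0
        res = pa.kabsch_superpose(x, y)
        fitted = x @ res.rotation.T + res.translation
        _, bt = struc.superimpose(y.astype(np.float32), x.astype(np.float32))
        bt_fitted = bt.apply(x.astype(np.float32))
        assert res.rmsd == pytest.approx(
            float(np.sqrt(np.mean(np.sum((bt_fitted - y) ** 2, axis=1)))),
            abs=1e-4,
        )
        np.testing.assert_allclose(fitted, bt_fitted, atol=1e-4)


class TestBuildOligomer:
    def test_self_templating_reproduces_template(self, rng):
        mono = pa.gen_helix_coords(20)
        template = pa.gen_c3_template(mono, radial_offset_angstrom=12.0)
        result = pa.build_oligomer(mono, template)
        np.testing.assert_allclose(
            result.atoms.coords, template.coords, atol=1e-6
        )
        assert all(r == pytest.approx(0.0, abs=1e-6)
                   for r in result.per_chain_rmsd.values())

    def test_single_chain_template_identity(self):
        mono = pa.gen_helix_coords(15)
        result = pa.build_oligomer(mono, mono)
        assert list(result.per_chain_rmsd) == ["A"]
        np.testing.assert_allclose(result.atoms.coords, mono.coords, atol=1e-8)

    def test_c3_symmetry_of_centroids(self):
        mono = pa.gen_helix_coords(20)
        template = pa.gen_c3_template(mono, radial_offset_angstrom=10.0)
        result = pa.build_oligomer(mono, template)
        atoms = result.atoms
        cents = np.array([
            atoms.coords[atoms.chain_ids == c].mean(axis=0) for c in "ABC"
        ])
        # rotating chain A's centroid by 120 degrees about z gives chain B's
        ang = 2 * math.pi / 3
        rot = np.array([
            [math.cos(ang), -math.sin(ang), 0],
            [math.sin(ang), math.cos(ang), 0],
            [0, 0, 1],
        ])
        np.testing.assert_allclose(rot @ cents[0], cents[1], atol=1e-6)
        np.testing.assert_allclose(rot @ cents[1], cents[2], atol=1e-6)

    def test_bad_residue_map_rejected(self):
        mono = pa.gen_helix_coords(10)
        template = pa.gen_c3_template(mono)
        with pytest.raises(ValueError, match="absent"):
            pa.build_oligomer(mono, template, residue_map={99: 1})


class TestHydrodynamicRadius:
    def test_single_bead_is_sigma(self):
        mass, vbar = 4187.6, 0.725
        sigma = (3 * mass * vbar / AVOGADRO * 1e21 / (4 * math.pi)) ** (1 / 3)
        got = pa.hydrodynamic_radius(np.zeros((1, 3)), mass, vbar)
        assert got == pytest.approx(sigma, rel=1e-12)

    def test_touching_dimer_four_thirds_sigma(self):
        mass, vbar = 4187.6, 0.725
        sigma = (3 * (mass / 2) * vbar / AVOGADRO * 1e21 / (4 * math.pi)) ** (1 / 3)
        coords = np.array([[0.0, 0, 0], [2 * sigma * 10, 0, 0]])  # Angstrom
        got = pa.hydrodynamic_radius(coords, mass, vbar)
        assert got == pytest.approx(4.0 / 3.0 * sigma, rel=1e-12)

    def test_line_of_beads_matches_double_sum_oracle(self):
        n, d_nm = 8, 5.0
        mass = 8000.0
        coords = np.column_stack(
            [np.arange(n) * d_nm * 10, np.zeros(n), np.zeros(n)]
        )
        sigma = (3 * (mass / n) * 0.725 / AVOGADRO * 1e21 / (4 * math.pi)) ** (1 / 3)
        s = 0.0
        for i in range(n):
            for j in range(n):
                if i != j:
                    s += 1.0 / (abs(i - j) * d_nm)
        expect = 1.0 / (1.0 / (n * sigma) + s / n**2)
        assert pa.hydrodynamic_radius(coords, mass) == pytest.approx(
            expect, rel=1e-12
        )

    def test_rigid_motion_invariance(self, rng):
        mono = pa.gen_helix_coords(25)
        base = pa.hydrodynamic_radius(mono, 4187.6)
        rot = random_rotation(rng)
        moved = pa.AtomSet(
            mono.chain_ids, mono.res_ids, mono.res_names, mono.atom_names,
            mono.coords @ rot.T + np.array([10.0, -30.0, 7.0]),
        )
        assert pa.hydrodynamic_radius(moved, 4187.6) == pytest.approx(
            base, rel=1e-12
        )

    def test_templated_trimer_larger_than_monomer(self):
        mono = pa.gen_helix_coords(39)
        template = pa.gen_c3_template(mono, radial_offset_angstrom=10.0)
        trimer = pa.build_oligomer(mono, template).atoms
        r_mono = pa.hydrodynamic_radius(mono, 4187.6)
        r_tri = pa.hydrodynamic_radius(trimer, 3 * 4187.6)
        assert r_tri > r_mono

    def test_coincident_beads_rejected(self):
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError, match="coincident"):
            pa.hydrodynamic_radius(coords, 1000.0)

    def test_calibration_factor_scales_result(self):
        mono = pa.gen_helix_coords(10)
        assert pa.hydrodynamic_radius(mono, 1000.0, calibration=1.1) == pytest.approx(
            1.1 * pa.hydrodynamic_radius(mono, 1000.0), rel=1e-12
        )
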