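"""Structure parsing, atom typing, and per-vertex chemical fields."""

import numpy as np
import pytest

from locsurf import chemistry as C
from locsurf import fixtures as fx
from locsurf.geometry import GeodesicPatch

MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
END
"""

GLC_PDB = "".join(
    f"HETATM{100 + i:>5}  C{i + 1:<2} GLC B 200    {float(i):8.3f}{0.0:8.3f}{0.0:8.3f}"
    f"{1.0:6.2f}{0.0:6.2f}          {'C':>2}\n"
    for i in range(12)
) + "END\n"


class TestReadStructure:
    def test_minimal_atom_only(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINI_PDB)
        s = C.read_structure(p)
        assert len(s.atoms) == 3
        assert s.ligand_instances == []
        assert s.atoms[1].element == "C"
        assert s.atoms[1].vdw_radius == pytest.approx(1.7)

    def test_hetatm_ligand_grouping(self, tmp_path):
        p = tmp_path / "glc.pdb"
        p.write_text(MINI_PDB.replace("END\n", "") + GLC_PDB)
        s = C.read_structure(p)
        assert len(s.atoms) == 3
        assert len(s.ligand_instances) == 1
        code, atoms = s.ligand_instances[0]
        assert code == "GLC" and len(atoms) == 12

    def test_truncated_coordinates_named_line(self, tmp_path):
        bad = MINI_PDB.splitlines(keepends=True)
        bad[1] = bad[1][:40] + "\n"  # cut inside the y coordinate field
        p = tmp_path / "bad.pdb"
        p.write_text("".join(bad))
        with pytest.raises(C.PDBParseError, match="line 2"):
            C.read_structure(p)

    def test_element_inferred_without_element_column(self, tmp_path):
        p = tmp_path / "noel.pdb"
        p.write_text("ATOM      1  OG  SER A   1       0.000   0.000   0.000\nEND\n")
        s = C.read_structure(p)
        assert s.atoms[0].element == "O"

    def test_pdb_roundtrip(self, tmp_path, tiny_structure):
        p = C.write_pdb(tiny_structure, tmp_path / "round.pdb")
        back = C.read_structure(p)
        assert [a.name for a in back.atoms] == [a.name for a in tiny_structure.atoms]
        np.testing.assert_allclose(back.positions, tiny_structure.positions, atol=1e-3)


class TestClassifyAtoms:
    @pytest.mark.parametrize(
        "res,name,expected,not_expected",
        [
            ("SER", "OG", {"hydroxyl_sidechain", "hbond_donor", "hbond_acceptor"}, set()),
            ("ALA", "N", {"N_backbone", "hbond_donor"}, set()),
            ("PRO", "N", {"N_backbone"}, {"hbond_donor"}),
            ("TRP", "CZ2", {"aromatic_sidechain", "trp_sidechain"}, set()),
            ("ASP", "OD1", {"charged_O_sidechain", "hbond_acceptor"}, set()),
            ("LYS", "NZ", {"charged_N_sidechain", "hbond_donor"}, set()),
            ("CYS", "SG", {"S_sidechain"}, set()),
            ("ASN", "ND2", {"amide_N_sidechain", "hbond_donor"}, set()),
            ("GLY", "CA", {"non_polar_backbone"}, {"aliphatic_sidechain"}),
            ("HIS", "ND1", {"aromatic_sidechain", "charged_N_sidechain",
                            "hbond_donor", "hbond_acceptor"}, set()),
        ],
    )
    def test_rule_table(self, res, name, expected, not_expected):
        cats = C._atom_categories(res, name)
        assert expected <= cats
        assert not (not_expected & cats)

    def test_unknown_residue_uncategorized(self, tiny_structure, caplog):
        tiny_structure.atoms[0].residue_name = "XYZ"
        with caplog.at_level("WARNING"):
            assignment = C.classify_atoms(tiny_structure)
        assert assignment.per_atom[0] == frozenset()
        tiny_structure.atoms[0].residue_name = "ALA"

    def test_hydroxyls_are_both_donor_and_acceptor(self):
        # OH groups are a subset of both the donor and the acceptor sets
        for res, name in [("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")]:
            cats = C._atom_categories(res, name)
            assert {"hydroxyl_sidechain", "hbond_donor", "hbond_acceptor"} <= cats


class TestCategoryDistances:
    def test_single_category_hit_and_sentinels(self, tiny_structure):
        assignment = C.classify_atoms(tiny_structure)
        point = np.array([0.0, 0.0, 0.0])  # 3 Å from the SER OG at (0,3,0)
        d = C.category_distances(point, tiny_structure, assignment)
        idx = C.CATEGORIES.index("hydroxyl_sidechain")
        assert d[idx] == pytest.approx(3.0)
        # no tryptophan anywhere: capped sentinel
        assert d[C.CATEGORIES.index("trp_sidechain")] == C.DISTANCE_CAP

    def test_nearest_wins(self, tiny_structure):
        assignment = C.classify_atoms(tiny_structure)
        extra = C.Atom(serial=9, name="OD2", element="O", residue_name="ASP",
                       chain="A", residue_seq=5, position=np.array([0.0, 0.0, 5.0]))
        tiny_structure.atoms.append(extra)
        try:
            assignment = C.classify_atoms(tiny_structure)
            d = C.category_distances(np.zeros(3), tiny_structure, assignment)
            assert d[C.CATEGORIES.index("charged_O_sidechain")] == pytest.approx(2.0)
        finally:
            tiny_structure.atoms.pop()

    def test_monotone_under_closer_atom(self, tiny_structure):
        assignment = C.classify_atoms(tiny_structure)
        before = C.category_distances(np.zeros(3), tiny_structure, assignment)
        closer = C.Atom(serial=10, name="SG", element="S", residue_name="CYS",
                        chain="A", residue_seq=6, position=np.array([1.0, 0.0, 0.0]))
        tiny_structure.atoms.append(closer)
        try:
            after = C.category_distances(
                np.zeros(3), tiny_structure, C.classify_atoms(tiny_structure))
        finally:
            tiny_structure.atoms.pop()
        assert np.all(after <= before + 1e-12)

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            C.category_distances(np.zeros(3), C.Structure(atoms=[]),
                                 C.CategoryAssignment(per_atom=[]))


class TestHydropathy:
    def _mesh_over(self, z=3.0):
        return fx.plane_mesh(extent=6.0)

    def test_poly_ile_surface(self):
        mesh = self._mesh_over()
        atoms = [
            C.Atom(serial=i + 1, name="CD1", element="C", residue_name="ILE",
                   chain="A", residue_seq=i + 1,
                   position=np.array([x, y, -2.0]))
            for i, (x, y) in enumerate([(-2, -2), (2, -2), (-2, 2), (2, 2), (0, 0)])
        ]
        h = C.hydropathy_field(mesh, C.Structure(atoms=atoms))
        assert np.all(h == pytest.approx(4.5))

    def test_poly_arg_surface(self):
        mesh = self._mesh_over()
        atoms = [
            C.Atom(serial=1, name="NH1", element="N", residue_name="ARG",
                   chain="A", residue_seq=1, position=np.array([0.0, 0.0, -2.0]))
        ]
        h = C.hydropathy_field(mesh, C.Structure(atoms=atoms))
        assert np.all(h == pytest.approx(-4.5))

    def test_tie_breaks_to_lower_serial(self):
        mesh = self._mesh_over()
        mk = lambda serial, res, x: C.Atom(
            serial=serial, name="CA", element="C", residue_name=res,
            chain="A", residue_seq=serial, position=np.array([x, 0.0, -2.0]))
        # two atoms mirror-symmetric about every vertex column x=0
        struct = C.Structure(atoms=[mk(2, "ILE", 5.0), mk(1, "ARG", -5.0)])
        h = C.hydropathy_field(mesh, struct)
        on_axis = np.abs(mesh.vertices[:, 0]) < 1e-9
        if on_axis.any():
            assert np.all(h[on_axis] == pytest.approx(-4.5))  # serial 1 = ARG

    def test_no_atoms_rejected(self):
        with pytest.raises(ValueError):
            C.hydropathy_field(self._mesh_over(), C.Structure(atoms=[]))


class TestPotential:
    def _grid(self, values, spacing=1.0, origin=(-2, -2, -2)):
        return C.PotentialGrid(origin=np.array(origin, float),
                               spacing=np.array([spacing] * 3), values=values)

    def test_constant_grid(self):
        g = self._grid(np.full((5, 5, 5), 3.25))
        pts = np.random.default_rng(0).uniform(-2, 2, size=(20, 3))
        np.testing.assert_allclose(C.sample_potential(g, pts), 3.25)

    def test_linear_field_exact(self):
        x = np.arange(5) - 2.0
        vals = np.broadcast_to(2.0 * x[:, None, None] + 1.0, (5, 5, 5)).copy()
        g = self._grid(vals)
        pts = np.random.default_rng(1).uniform(-1.9, 1.9, size=(30, 3))
        np.testing.assert_allclose(C.sample_potential(g, pts), 2.0 * pts[:, 0] + 1.0,
                                   atol=1e-12)

    def test_point_charge_grid_matches_coulomb(self):
        # fine grid of q/r sampled off-lattice within 2%
        ax = np.linspace(1.0, 3.0, 41)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        R = np.sqrt(X**2 + Y**2 + Z**2)
        g = C.PotentialGrid(origin=np.array([1.0, 1.0, 1.0]),
                            spacing=np.array([0.05] * 3), values=1.0 / R)
        pts = np.random.default_rng(2).uniform(1.2, 2.8, size=(50, 3))
        ref = 1.0 / np.linalg.norm(pts, axis=1)
        got = C.sample_potential(g, pts)
        assert np.abs(got / ref - 1).max() < 0.02

    def test_outside_points_clamped_with_warning(self):
        g = self._grid(np.full((5, 5, 5), 1.0))
        with pytest.warns(UserWarning, match="outside"):
            out = C.sample_potential(g, np.array([[10.0, 0.0, 0.0]]))
        assert out[0] == pytest.approx(1.0)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            self._grid(np.zeros((1, 5, 5)))

    def test_dx_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        g = self._grid(rng.normal(size=(4, 5, 6)))
        p = C.write_dx(g, tmp_path / "pot.dx")
        back = C.read_dx(p)
        np.testing.assert_allclose(back.values, g.values, rtol=1e-6)
        np.testing.assert_allclose(back.origin, g.origin)


class TestPatchAverage:
    def _patch(self, members, dists, weights):
        return GeodesicPatch(center=int(members[0]), radius=float(max(dists)),
                             members=np.asarray(members), distances=np.asarray(dists),
                             weights=np.asarray(weights, float))

    def test_constant_field(self):
        patch = self._patch([0, 1, 2], [0, 1, 2], [0.5, 1.0, 2.0])
        assert C.patch_average(np.full(5, 7.5), patch) == pytest.approx(7.5)

    def test_field_outside_patch_ignored(self):
        patch = self._patch([0, 1], [0, 1], [1.0, 1.0])
        field = np.array([0.0, 0.0, 99.0, 99.0])
        assert C.patch_average(field, patch) == 0.0

    def test_hand_computed_three_vertex(self):
        patch = self._patch([0, 1, 2], [0, 1, 2], [1.0, 2.0, 3.0])
        field = np.array([2.0, 4.0, 8.0])
        assert C.patch_average(field, patch) == pytest.approx((2 + 8 + 24) / 6.0)

    def test_within_field_range(self):
        rng = np.random.default_rng(4)
        field = rng.normal(size=10)
        patch = self._patch(np.arange(10), np.linspace(0, 2, 10), rng.uniform(0.1, 1, 10))
        avg = C.patch_average(field, patch)
        assert field.min() - 1e-12 <= avg <= field.max() + 1e-12

    def test_zero_weights_rejected(self):
        patch = self._patch([0, 1], [0, 1], [0.0, 0.0])
        with pytest.raises(ValueError):
            C.patch_average(np.ones(2), patch)
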