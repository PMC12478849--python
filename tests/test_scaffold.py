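"""Idealized 3D scaffolds, surface paths and superposition RMSD."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from g4topo.scaffold import (
    Scaffold,
    ScaffoldParams,
    build_scaffold,
    kabsch_rmsd,
    loop_attachment_pair,
    propeller_path_table,
    shortest_surface_path,
    write_scaffold_pdb,
)
from g4topo.topology import parse_topology


class TestBuildScaffold:
    @pytest.mark.parametrize("n,expected", [(2, 8), (3, 12)])
    def test_anchor_counts(self, n, expected):
        scaffold = build_scaffold(n)
        assert scaffold.anchors.shape == (4, n, 3)
        assert scaffold.anchors.size == expected * 3

    def test_interlevel_distance_matches_cylinder_chord(self):
        """Distance between successive anchors of one tract equals the
        rise combined with the twist chord, sqrt(rise^2 + (2r sin(t/2))^2)."""
        p = ScaffoldParams()
        scaffold = build_scaffold(2, "RH", p)
        chord = 2 * p.radius_nm * math.sin(math.radians(p.twist_deg) / 2)
        expected = math.hypot(p.rise_nm, chord)
        for c in range(4):
            d = np.linalg.norm(scaffold.anchors[c, 1] - scaffold.anchors[c, 0])
            assert d == pytest.approx(expected)

    def test_lh_is_mirror_of_rh(self):
        """Reflection through the xz-plane maps the RH scaffold onto the
        LH one (corner c maps to corner -c mod 4)."""
        rh = build_scaffold(3, "RH")
        lh = build_scaffold(3, "LH")
        mirrored = rh.anchors * np.array([1.0, -1.0, 1.0])
        for c in range(4):
            assert np.allclose(lh.anchors[(-c) % 4], mirrored[c])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_scaffold(4)
        with pytest.raises(ValueError):
            ScaffoldParams(rise_nm=-1.0)


class TestAttachmentPair:
    def test_propeller_spans_opposite_levels_of_adjacent_corners(self):
        topo = parse_topology("-p-p-p")
        scaffold = build_scaffold(3)
        a, b = loop_attachment_pair(scaffold, topo.trace, "I")
        assert a[2] == pytest.approx(2 * scaffold.params.rise_nm)  # top exit
        assert b[2] == pytest.approx(0.0)  # bottom entry

    def test_lateral_position_rejected(self):
        topo = parse_topology("-l-p-p")
        scaffold = build_scaffold(3)
        with pytest.raises(ValueError, match="not a propeller"):
            loop_attachment_pair(scaffold, topo.trace, "I")


class TestSurfacePath:
    def test_closed_form_quarter_turn(self):
        scaffold = build_scaffold(3)
        r = scaffold.params.radius_nm + scaffold.params.probe_nm
        a = np.array([1.0, 0.0, 0.5])
        b = np.array([0.0, 1.0, 0.5])
        path = shortest_surface_path(scaffold, a, b, "counterclockwise")
        assert path.length_nm == pytest.approx(r * math.pi / 2)
        # the other winding traverses the complementary 3/4 turn
        path_cw = shortest_surface_path(scaffold, a, b, "clockwise")
        assert path_cw.length_nm == pytest.approx(r * 3 * math.pi / 2)

    def test_identical_endpoints_give_zero_length(self):
        scaffold = build_scaffold(3)
        a = np.array([1.0, 0.0, 0.0])
        assert shortest_surface_path(scaffold, a, a).length_nm == 0.0

    def test_length_at_least_straight_line(self):
        scaffold = build_scaffold(3)
        rng = np.random.default_rng(0)
        for _ in range(20):
            phi = rng.uniform(0, 2 * math.pi, size=2)
            z = rng.uniform(0, 0.68, size=2)
            a = np.array([math.cos(phi[0]), math.sin(phi[0]), z[0]])
            b = np.array([math.cos(phi[1]), math.sin(phi[1]), z[1]])
            for w in ("clockwise", "counterclockwise"):
                path = shortest_surface_path(scaffold, a, b, w)
                assert path.length_nm >= np.linalg.norm(b - a) - 1e-12

    def test_vertices_on_guard_cylinder(self):
        scaffold = build_scaffold(3)
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([0.0, -1.0, 0.68])
        path = shortest_surface_path(scaffold, a, b, "clockwise")
        radii = np.hypot(path.points[:, 0], path.points[:, 1])
        guard = scaffold.params.radius_nm + scaffold.params.probe_nm
        assert np.allclose(radii, guard)

    def test_sd_and_ld_populations_are_disjoint(self):
        table = propeller_path_table(3)
        sd = table.loc[table.geometry_label == "SD", "path_length_nm"]
        ld = table.loc[table.geometry_label == "LD", "path_length_nm"]
        assert len(table) == 68  # 34 propeller loops per helicity
        assert sd.max() < ld.min()

    def test_two_tetrad_ld_paths_shorter_than_three_tetrad(self):
        ld2 = propeller_path_table(2).query("geometry_label == 'LD'").path_length_nm
        ld3 = propeller_path_table(3).query("geometry_label == 'LD'").path_length_nm
        assert ld2.max() < ld3.min()


class TestKabschRMSD:
    def test_identical_and_rotated_sets_score_zero(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(8, 3))
        assert kabsch_rmsd(A, A) == pytest.approx(0.0, abs=1e-12)
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        assert kabsch_rmsd(A, A @ R.T + np.array([1.0, -2.0, 0.5])) == pytest.approx(
            0.0, abs=1e-9
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_superposition_oracle(self, seed):
        """Agree with MDAnalysis' superposition RMSD on noisy point sets."""
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        rng = np.random.default_rng(seed)
        A = rng.normal(size=(4, 3))
        B = A + rng.normal(scale=0.3, size=(4, 3))
        ours = kabsch_rmsd(A, B)
        theirs = mda_rmsd(A, B, center=True, superposition=True)
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_reflection_not_allowed(self):
        """A mirrored set does not score zero: only proper rotations."""
        rng = np.random.default_rng(3)
        A = rng.normal(size=(6, 3))
        mirrored = A * np.array([1.0, 1.0, -1.0])
        assert kabsch_rmsd(A, mirrored) > 0.1

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPathInvariance:
    def test_path_length_invariant_under_rigid_motion(self):
        """Rotating/translating the whole scaffold does not change any
        propeller path length (recomputed in the moved frame)."""
        base = propeller_path_table(3, helicities=("RH",))
        # rotating about z and shifting along z maps the cylinder to itself
        scaffold = build_scaffold(3)
        topo = parse_topology("+p+p+p")
        a, b = loop_attachment_pair(scaffold, topo.trace, "II")
        Rz = Rotation.from_euler("z", 1.234).as_matrix()
        shift = np.array([0.0, 0.0, 5.0])
        p0 = shortest_surface_path(scaffold, a, b, "clockwise")
        p1 = shortest_surface_path(scaffold, Rz @ a + shift, Rz @ b + shift, "clockwise")
        assert p1.length_nm == pytest.approx(p0.length_nm)
        assert len(base) == 34


class TestPdbExport:
    @pytest.mark.parametrize("n,expected_atoms", [(2, 8), (3, 12)])
    def test_atom_counts_and_roundtrip(self, tmp_path, n, expected_atoms):
        import biotite.structure.io.pdb as pdb

        scaffold = build_scaffold(n)
        path = tmp_path / f"scaffold{n}.pdb"
        write_scaffold_pdb(scaffold, str(path))
        text = path.read_text()
        assert text.count("\nATOM") + text.startswith("ATOM") == expected_atoms
        atoms = pdb.PDBFile.read(str(path)).get_structure(model=1)
        assert atoms.array_length() == expected_atoms
        assert sorted(set(atoms.chain_id)) == ["A", "B", "C", "D"]
        # PDB keeps 3 decimals in Angstrom
        ours = scaffold.anchors.reshape(-1, 3) * 10.0
        assert np.allclose(np.sort(atoms.coord, axis=0), np.sort(ours, axis=0), atol=1e-3)
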