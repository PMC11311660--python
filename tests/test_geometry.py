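import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noesypop.errors import DegenerateGeometryError, LookupLabelError, ParseError
from noesypop.geometry import (
    HBondGeometry,
    atom_distance,
    dihedral_angle,
    hbond_geometry,
    parse_pdb,
    parse_xyz,
    write_xyz,
)

from conftest import make_geometry, random_rotation


class TestParseXyz:
    def test_single_atom(self):
        geom = parse_xyz("1\n\nH 0 0 0\n")
        assert len(geom) == 1
        assert geom.atoms[0].element == "H"
        assert np.allclose(geom.atoms[0].position, 0.0)

    def test_count_mismatch_names_problem(self):
        with pytest.raises(ParseError, match="3"):
            parse_xyz("3\ncomment\nH 0 0 0\nH 1 0 0\n")

    def test_non_numeric_coordinate_names_line(self):
        with pytest.raises(ParseError, match="line 4"):
            parse_xyz("2\ncomment\nH 0 0 0\nC 1 zero 0\n")

    def test_label_column_and_synthesized_labels(self):
        geom = parse_xyz("2\n\nH 0 0 0 H12a\nH 1 0 0\n")
        assert geom.labels == ["H12a", "H1"]

    def test_roundtrip_preserves_positions(self, rng):
        pts = rng.normal(size=(5, 3))
        geom = make_geometry("g", [(f"A{i}", "C", p) for i, p in enumerate(pts)])
        back = parse_xyz(write_xyz(geom), conformer_id="g")
        assert np.allclose(back.positions, geom.positions, atol=1e-6)
        assert back.labels == geom.labels

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            parse_xyz("2\n\nH 0 0 0 Ha\nH 1 0 0 Ha\n")


class TestParsePdb:
    PDB = (
        "ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  O1 ALIG A   1       1.500   0.000   0.000  0.50  0.00           O\n"
        "ATOM      3  O1 BLIG A   1       1.600   0.000   0.000  0.50  0.00           O\n"
        "HETATM    4  F1  LIG A   1       0.000   2.000   0.000  1.00  0.00           F\n"
    )

    def test_first_altloc_wins(self):
        geom = parse_pdb(self.PDB)
        assert geom.labels == ["C1", "O1", "F1"]
        assert np.isclose(geom.position("O1")[0], 1.5)

    def test_no_records_is_error(self):
        with pytest.raises(ParseError):
            parse_pdb("REMARK nothing here\n")


class TestDistanceAndDihedral:
    def test_axis_distance(self):
        geom = make_geometry("g", [("A", "H", (0, 0, 0)), ("B", "H", (0, 0, 2))])
        assert atom_distance(geom, "A", "B") == pytest.approx(2.0)
        assert atom_distance(geom, "A", "A") == 0.0

    def test_unknown_label(self):
        geom = make_geometry("g", [("A", "H", (0, 0, 0)), ("B", "H", (1, 0, 0))])
        with pytest.raises(LookupLabelError):
            atom_distance(geom, "A", "Z")

    def test_distance_matches_brute_force(self, rng):
        p, q = rng.normal(size=(2, 3))
        geom = make_geometry("g", [("A", "H", p), ("B", "H", q)])
        assert atom_distance(geom, "A", "B") == pytest.approx(
            math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))
        )

    @pytest.mark.parametrize(
        "fourth,expected",
        [((1.0, 0.0, 2.5), 0.0), ((-1.0, 0.0, 2.5), 180.0)],
        ids=["cis", "trans"],
    )
    def test_planar_limits(self, fourth, expected):
        geom = make_geometry(
            "g",
            [
                ("A", "C", (1, 0, -1)),
                ("B", "C", (0, 0, 0)),
                ("C", "C", (0, 0, 1.5)),
                ("D", "C", fourth),
            ],
        )
        assert abs(dihedral_angle(geom, "A", "B", "C", "D")) == pytest.approx(expected)

    def test_matches_independent_atan2_oracle(self, butane_like):
        # independent construction: angle between plane normals, signed by
        # the b->c direction
        p = {lbl: butane_like.position(lbl) for lbl in "C1 C2 C3 C4".split()}
        b1, b2, b3 = p["C2"] - p["C1"], p["C3"] - p["C2"], p["C4"] - p["C3"]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        cosphi = n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2))
        sign = np.sign(np.cross(n1, n2) @ b2)
        expected = math.degrees(sign * math.acos(np.clip(cosphi, -1, 1)))
        got = dihedral_angle(butane_like, "C1", "C2", "C3", "C4")
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(-60.0, abs=1e-9)

    def test_collinear_is_degenerate(self):
        geom = make_geometry(
            "g",
            [
                ("A", "C", (1, 0, 0)),
                ("B", "C", (0, 0, 0)),
                ("C", "C", (0, 0, 1)),
                ("D", "C", (0, 0, 2)),
            ],
        )
        with pytest.raises(DegenerateGeometryError):
            dihedral_angle(geom, "A", "B", "C", "D")

    def test_rigid_motion_invariance_and_mirror_sign_flip(self, butane_like, rng):
        rot = random_rotation(rng)
        shift = rng.normal(size=3) * 10
        moved = make_geometry(
            "m", [(a.label, a.element, rot @ a.position + shift) for a in butane_like.atoms]
        )
        mirrored = make_geometry(
            "r", [(a.label, a.element, a.position * np.array([1, -1, 1])) for a in butane_like.atoms]
        )
        ref = dihedral_angle(butane_like, "C1", "C2", "C3", "C4")
        assert dihedral_angle(moved, "C1", "C2", "C3", "C4") == pytest.approx(ref, abs=1e-9)
        assert dihedral_angle(mirrored, "C1", "C2", "C3", "C4") == pytest.approx(-ref, abs=1e-9)


class TestHBondGeometry:
    def test_collinear(self):
        geom = make_geometry(
            "g", [("X", "O", (0, 0, 0)), ("H", "H", (0, 0, 1)), ("Y", "O", (0, 0, 3))]
        )
        hb = hbond_geometry(geom, "X", "H", "Y")
        assert (hb.r_xy, hb.r_hy) == pytest.approx((3.0, 2.0))
        assert hb.angle_xhy == pytest.approx(180.0)

    def test_right_angle(self):
        geom = make_geometry(
            "g", [("X", "N", (1, 0, 0)), ("H", "H", (0, 0, 0)), ("Y", "O", (0, 2, 0))]
        )
        assert hbond_geometry(geom, "X", "H", "Y").angle_xhy == pytest.approx(90.0)

    def test_coincident_hydrogen_degenerate(self):
        geom = make_geometry(
            "g", [("X", "O", (0, 0, 0)), ("H", "H", (0, 0, 0)), ("Y", "O", (0, 0, 3))]
        )
        with pytest.raises(DegenerateGeometryError):
            hbond_geometry(geom, "X", "H", "Y")

    def test_invariants_enforced_on_construction(self):
        with pytest.raises(DegenerateGeometryError):
            HBondGeometry("X", "H", "Y", r_xy=1.0, r_hy=2.0, angle_xhy=120.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_descriptors_rigid_invariant(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(3, 3)) * 3
        if min(np.linalg.norm(pts[1] - pts[0]), np.linalg.norm(pts[1] - pts[2])) < 1e-3:
            return
        geom = make_geometry("g", [("X", "O", pts[0]), ("H", "H", pts[1]), ("Y", "O", pts[2])])
        rot = random_rotation(rng)
        shift = rng.normal(size=3)
        moved = make_geometry(
            "m", [(a.label, a.element, rot @ a.position + shift) for a in geom.atoms]
        )
        try:
            hb0 = hbond_geometry(geom, "X", "H", "Y")
        except DegenerateGeometryError:
            return  # random triangle violates the H-bond shape invariant
        hb1 = hbond_geometry(moved, "X", "H", "Y")
        assert hb1.r_xy == pytest.approx(hb0.r_xy, abs=1e-9)
        assert hb1.r_hy == pytest.approx(hb0.r_hy, abs=1e-9)
        assert hb1.angle_xhy == pytest.approx(hb0.angle_xhy, abs=1e-7)
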