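"""Dihedral angles, torsion tables and circular angle arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from ecdkit import (
    BackboneTorsionTable,
    backbone_map_from_pdb,
    backbone_torsions,
    circular_difference,
    dihedral,
    helix_deviation,
)
from ecdkit.reference import GHRP5_CONFORMER_TORSIONS
from ecdkit.synth import BackboneBuildSpec, backbone_from_torsion_table, build_backbone

angles = st.floats(min_value=-720.0, max_value=720.0, allow_nan=False)


class TestDihedral:
    @pytest.mark.parametrize(
        "p4,expected",
        [((1, 1, 0), 0.0), ((-1, 1, 0), 180.0), ((0, 1, 1), -90.0), ((0, 1, -1), 90.0)],
    )
    def test_planar_and_perpendicular(self, p4, expected):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), p4) == pytest.approx(expected)

    def test_result_in_half_open_interval(self, rng):
        for _ in range(200):
            pts = rng.normal(size=(4, 3))
            try:
                d = dihedral(*pts)
            except ValueError:
                continue
            assert -180.0 < d <= 180.0

    def test_rigid_motion_invariance_and_mirror_negation(self, rng):
        for _ in range(100):
            pts = rng.normal(size=(4, 3)) * 3.0
            try:
                d0 = dihedral(*pts)
            except ValueError:
                continue
            # random rotation (QR of a Gaussian matrix) + translation
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            shift = rng.normal(size=3) * 10.0
            moved = pts @ q.T + shift
            assert dihedral(*moved) == pytest.approx(d0, abs=1e-8)
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            assert dihedral(*mirrored) == pytest.approx(-d0, abs=1e-8) or (
                abs(d0) == pytest.approx(180.0, abs=1e-8)
            )

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestBackboneTorsions:
    def test_ideal_helix_round_trip(self):
        geom, bmap = backbone_from_torsion_table([(-57.0, -47.0)] * 4)
        table = backbone_torsions(geom, bmap)
        assert len(table) == 4
        assert np.allclose(table.phi_deg, -57.0, atol=1e-6)
        assert np.allclose(table.psi_deg, -47.0, atol=1e-6)

    def test_random_torsion_round_trip(self, rng):
        for _ in range(100):
            pairs = [tuple(rng.uniform(-179.0, 179.0, 2)) for _ in range(4)]
            geom, bmap = backbone_from_torsion_table(pairs)
            table = backbone_torsions(geom, bmap)
            err = max(
                max(circular_difference(p, tp), circular_difference(s, ts))
                for (p, s), (tp, ts) in zip(pairs, table.as_pairs())
            )
            assert err < 1e-6

    def test_reference_conformer_tables_reproduced(self):
        for name, pairs in GHRP5_CONFORMER_TORSIONS.items():
            geom, bmap = backbone_from_torsion_table(pairs)
            table = backbone_torsions(geom, bmap)
            for (phi, psi), (tphi, tpsi) in zip(pairs, table.as_pairs()):
                assert tphi == pytest.approx(phi, abs=0.1), name
                assert tpsi == pytest.approx(psi, abs=0.1), name

    def test_omega_is_trans(self):
        geom, bmap = backbone_from_torsion_table([(-57.0, -47.0)] * 4)
        coords = geom.coords_angstrom
        for k in range(1, 5):  # CA(k)-C(k)-N(k+1)-CA(k+1)
            ca, c = 3 * (k - 1) + 1, 3 * (k - 1) + 2
            n_next = 3 * k
            ca_next = 3 * k + 1 if k < 4 else None
            if ca_next is not None:
                omega = dihedral(coords[ca], coords[c], coords[n_next], coords[ca_next])
                assert abs(omega) == pytest.approx(180.0, abs=1e-6)

    def test_pdb_derived_map_matches_explicit(self, tmp_path):
        from ecdkit.io import read_geometry, write_pdb

        geom, bmap = backbone_from_torsion_table(GHRP5_CONFORMER_TORSIONS["mic-II"])
        path = tmp_path / "conf.pdb"
        write_pdb(geom, path)
        again = read_geometry(path, "pdb")
        table = backbone_torsions(again, backbone_map_from_pdb(again))
        expected = backbone_torsions(geom, bmap)
        # PDB stores coordinates to 1e-3 A; torsions survive to ~0.05 deg
        assert np.allclose(table.phi_deg, expected.phi_deg, atol=0.1)
        assert np.allclose(table.psi_deg, expected.psi_deg, atol=0.1)

    def test_free_acid_drops_last_psi(self):
        spec = BackboneBuildSpec(5, ((-57.0, -47.0),) * 4, c_terminal_amide=False)
        geom, bmap = build_backbone(spec)
        assert len(backbone_torsions(geom, bmap)) == 3

    def test_single_residue_rejected(self):
        with pytest.raises(ValueError):
            BackboneBuildSpec(1, ())


class TestCircularDifference:
    def test_wraparound(self):
        assert circular_difference(170.0, -170.0) == pytest.approx(20.0)

    @given(a=angles, b=angles)
    @hsettings(max_examples=100, derandomize=True)
    def test_symmetric_bounded_shift_invariant(self, a, b):
        d = circular_difference(a, b)
        assert 0.0 <= d <= 180.0
        assert d == pytest.approx(circular_difference(b, a), abs=1e-9)
        assert d == pytest.approx(circular_difference(a + 360.0, b), abs=1e-6)
        assert circular_difference(a, a) == pytest.approx(0.0, abs=1e-9)

    @given(a=angles, b=angles, c=angles)
    @hsettings(max_examples=100, derandomize=True)
    def test_triangle_inequality(self, a, b, c):
        assert circular_difference(a, c) <= (
            circular_difference(a, b) + circular_difference(b, c) + 1e-9
        )

    def test_mic_conformer_pair_differs_only_at_terminal_linkage(self):
        """The two micelle helix-like conformers share the first three
        linkages but diverge at the last one."""
        mi = GHRP5_CONFORMER_TORSIONS["mic-I"]
        miii = GHRP5_CONFORMER_TORSIONS["mic-III"]
        diffs = [
            (circular_difference(p1, p2), circular_difference(s1, s2))
            for (p1, s1), (p2, s2) in zip(mi, miii)
        ]
        inner = [d for pair in diffs[:3] for d in pair]
        assert max(inner) == pytest.approx(5.5, abs=1e-9)
        assert diffs[3][1] == pytest.approx(56.4, abs=1e-9)


class TestHelixDeviation:
    def test_ideal_helix_is_zero(self):
        table = BackboneTorsionTable([-57.0] * 4, [-47.0] * 4)
        assert helix_deviation(table) == 0.0

    def test_single_pair_closed_form(self):
        # phi on target, psi 180 deg away -> RMS over the two angles
        table = BackboneTorsionTable([-57.0], [133.0])
        assert helix_deviation(table) == pytest.approx(180.0 / np.sqrt(2.0), abs=1e-9)

    def test_reference_conformers_are_far_from_canonical_helix(self):
        """None of the five reference conformers has canonical alpha-helix
        backbone angles: a D/L-mixed pentapeptide cannot form one."""
        for name, pairs in GHRP5_CONFORMER_TORSIONS.items():
            assert helix_deviation(BackboneTorsionTable(*zip(*pairs))) > 60.0, name

    def test_structurally_paired_conformers_are_nearest_neighbors(self):
        """aq-I/mic-II and mic-I/mic-III, described as sharing backbone
        orientations, are by far the closest pairs in mean circular
        distance over their torsion tables."""

        def mean_dist(a, b):
            return np.mean(
                [
                    circular_difference(x, y)
                    for (p1, s1), (p2, s2) in zip(
                        GHRP5_CONFORMER_TORSIONS[a], GHRP5_CONFORMER_TORSIONS[b]
                    )
                    for x, y in ((p1, p2), (s1, s2))
                ]
            )

        import itertools

        dists = {
            pair: mean_dist(*pair)
            for pair in itertools.combinations(sorted(GHRP5_CONFORMER_TORSIONS), 2)
        }
        closest = sorted(dists, key=dists.get)[:2]
        assert set(closest) == {("aq-I", "mic-II"), ("mic-I", "mic-III")}
        assert all(dists[p] < 15.0 for p in closest)
        assert all(d > 35.0 for p, d in dists.items() if p not in closest)
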