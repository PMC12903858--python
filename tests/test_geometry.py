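"""Radius of gyration, torsions, CH···O geometry, inter-residue distances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import foldsaxs as fs
from foldsaxs.geometry import dihedral_series, min_interresidue_distance
from foldsaxs.models import Atom, MolecularModel, TrajectoryFrames


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert fs.radius_of_gyration(np.array([[3.0, -2.0, 7.0]]), np.array([5.0])) == 0.0

    def test_two_unit_weight_atoms_give_half_distance(self):
        d = 1.7
        frame = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        assert fs.radius_of_gyration(frame, np.ones(2)) == pytest.approx(d / 2)

    def test_collinear_beads_match_direct_summation_oracle(self):
        n, spacing = 9, 0.5
        frame = np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
        w = np.ones(n)
        # independent oracle: direct summation over the 9 points
        center = frame.mean(axis=0)
        expected = np.sqrt(((frame - center) ** 2).sum(axis=1).mean())
        assert fs.radius_of_gyration(frame, w) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(spacing * np.sqrt((n**2 - 1) / 12), abs=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(fs.ValidationError):
            fs.radius_of_gyration(np.zeros((3, 3)), np.zeros(3))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        frame = rng.normal(size=(12, 3))
        w = rng.uniform(0.5, 2.0, size=12)
        rg0 = fs.radius_of_gyration(frame, w)
        for seed in range(5):
            rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            shift = rng.normal(size=3) * 10
            moved = frame @ rot.T + shift
            assert fs.radius_of_gyration(moved, w) == pytest.approx(rg0, abs=1e-10)


class TestRgSeries:
    def _toy_traj(self, frames):
        atoms = [
            Atom("C1", "C", 12.011),
            Atom("O1", "O", 15.999),
            Atom("H1", "H", 1.008),
        ]
        model = MolecularModel(atoms, frames[0])
        return TrajectoryFrames(model, frames, 0.1)

    def test_identical_frames_give_equal_values(self):
        frame = np.array([[0.0, 0, 0], [0.3, 0, 0], [0.3, 0.3, 0]])
        series = fs.rg_series(self._toy_traj([frame] * 3))
        assert len(series) == 3
        assert np.ptp(series.values) == 0.0

    def test_mass_vs_electron_weighting_differ_on_asymmetric_molecule(self):
        # direct-summation oracle for both weightings
        frame = np.array([[0.0, 0, 0], [0.3, 0, 0], [0.9, 0.2, 0]])
        traj = self._toy_traj([frame])
        out = {}
        for weighting, w in (("mass", [12.011, 15.999, 1.008]), ("electron", [6, 8, 1])):
            w = np.asarray(w, float)
            center = (w[:, None] * frame).sum(0) / w.sum()
            expected = np.sqrt((w * ((frame - center) ** 2).sum(1)).sum() / w.sum())
            series = fs.rg_series(traj, weighting)
            assert series.values[0] == pytest.approx(expected, abs=1e-12)
            out[weighting] = series.values[0]
        assert out["mass"] != pytest.approx(out["electron"], abs=1e-6)
        assert all(v >= 0 for v in out.values())

    def test_rigid_compact_conformer_gives_constant_series(self):
        spec = fs.TwoStateSpec(occupancy_folded=1.0, jitter_sd=0.0, seed=1)
        with pytest.warns(UserWarning):
            traj, _ = fs.generate_two_state_trajectory(spec, 5, 0.1)
        series = fs.rg_series(traj)
        assert np.ptp(series.values) == pytest.approx(0.0, abs=1e-12)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert fs.dihedral((1, 1, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0)) == pytest.approx(0.0)

    def test_planar_trans_is_180(self):
        assert fs.dihedral((1, 1, 0), (1, 0, 0), (2, 0, 0), (2, -1, 0)) == pytest.approx(180.0)

    def test_right_handed_quarter_turn(self):
        # frozen from an independent rotation-matrix oracle
        assert fs.dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (0, 1, 1)) == pytest.approx(-90.0)

    def test_reversal_preserves_value_and_mirror_flips_sign(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pts = rng.normal(size=(4, 3))
            ang = fs.dihedral(*pts)
            assert fs.dihedral(*pts[::-1]) == pytest.approx(ang, abs=1e-9)
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            assert fs.dihedral(*mirrored) == pytest.approx(-ang, abs=1e-9)

    def test_collinear_points_rejected(self):
        with pytest.raises(fs.ValidationError):
            fs.dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_series_on_trajectory(self):
        frame = np.array([[1.0, 0, 0], [0, 0, 0], [0, 1.0, 0], [0, 1.0, 1.0], [2, 2, 2]])
        atoms = [Atom(f"C{i}", "C", 12.011) for i in range(5)]
        traj = TrajectoryFrames(MolecularModel(atoms, frame), [frame, frame], 0.1)
        series = dihedral_series(traj, (0, 1, 2, 3), (1, 2, 3, 4))
        np.testing.assert_allclose(series.phi, [-90.0, -90.0])
        assert series.atom_quadruples[0] == (0, 1, 2, 3)


class TestHBond:
    def test_collinear_favorable_contact(self):
        g = fs.hbond_geometry((0, 0, 0), (0.11, 0, 0), (0.35, 0, 0))
        assert g.dha_angle == pytest.approx(180.0)
        assert g.donor_acceptor_distance == pytest.approx(0.35)
        assert g.favorable

    def test_long_distance_unfavorable_despite_good_angle(self):
        g = fs.hbond_geometry((0, 0, 0), (0.109, 0.019, 0), (0.45, 0, 0))
        assert g.dha_angle > 150.0
        assert not g.favorable

    def test_right_angle_at_h_unfavorable(self):
        g = fs.hbond_geometry((0, 0.1, 0), (0, 0, 0), (0.2, 0, 0))
        assert g.dha_angle == pytest.approx(90.0)
        assert not g.favorable

    def test_boundary_values_are_strictly_excluded(self):
        # exactly 0.4 nm: not favorable even at 180 degrees
        at_dist = fs.hbond_geometry((0, 0, 0), (0.1, 0, 0), (0.4, 0, 0))
        assert at_dist.donor_acceptor_distance == pytest.approx(0.4)
        assert not at_dist.favorable
        # exactly 150 degrees at short distance: not favorable
        h = np.zeros(3)
        c = np.array([0.1, 0.0, 0.0])
        theta = np.radians(150.0)
        o = 0.25 * np.array([np.cos(theta), np.sin(theta), 0.0])
        at_angle = fs.hbond_geometry(c, h, o)
        assert at_angle.dha_angle == pytest.approx(150.0, abs=1e-9)
        assert not at_angle.favorable

    def test_coincident_points_rejected(self):
        with pytest.raises(fs.ValidationError):
            fs.hbond_geometry((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_occupancy_fraction_matches_counting_oracle(self):
        good = np.array([[0.0, 0, 0], [0.11, 0, 0], [0.35, 0, 0]])
        bad = np.array([[0.0, 0, 0], [0.11, 0, 0], [0.55, 0, 0]])
        atoms = [Atom("C1", "C", 12.011), Atom("H1", "H", 1.008), Atom("O1", "O", 15.999)]
        for frames, expected in (
            ([good] * 4, 1.0),
            ([bad] * 4, 0.0),
            ([good, bad, good, bad], 0.5),
        ):
            traj = TrajectoryFrames(MolecularModel(atoms, frames[0]), frames, 0.1)
            geoms, fraction = fs.hbond_occupancy_map(traj, 0, 1, 2)
            assert fraction == sum(g.favorable for g in geoms) / len(geoms) == expected


class TestMinInterresidueDistance:
    def test_shared_coordinate_gives_zero(self):
        frame = np.array([[0.0, 0, 0], [1, 0, 0], [0, 0, 0], [2, 2, 2]])
        assert min_interresidue_distance(frame, [0, 1], [2, 3]) == 0.0

    def test_two_single_atoms(self):
        frame = np.array([[0.0, 0, 0], [0, 1.2, 0]])
        assert min_interresidue_distance(frame, [0], [1]) == pytest.approx(1.2)

    def test_matches_brute_force_over_grid_sets(self):
        rng = np.random.default_rng(9)
        frame = rng.normal(size=(6, 3))
        a, b = [0, 1, 2], [3, 4, 5]
        brute = min(np.linalg.norm(frame[i] - frame[j]) for i in a for j in b)
        assert min_interresidue_distance(frame, a, b) == pytest.approx(brute, abs=1e-12)

    def test_overlapping_or_empty_sets_rejected(self):
        frame = np.zeros((3, 3))
        with pytest.raises(fs.ValidationError):
            min_interresidue_distance(frame, [0, 1], [1, 2])
        with pytest.raises(fs.ValidationError):
            min_interresidue_distance(frame, [], [1])
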