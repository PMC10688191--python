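"""Atom selections, triplet enumeration, angles, RMSD, and distances."""

import math

import numpy as np
import pytest

import switchscan as ss
from switchscan.geometry import STANDARD_RESIDUES, TrajectorySet


# printed angle-count constraints that pin the selection table
PINNED_COUNTS = {
    "ALA": (5, 10),
    "SER": (6, 20),
    "TYR": (7, 35),
    "ILE": (8, 56),
    "MET": (8, 56),
    "GLN": (9, 84),
    "ARG": (10, 120),
}


class TestSelectedAtoms:
    @pytest.mark.parametrize("name,expected", sorted(PINNED_COUNTS.items()))
    def test_pinned_atom_and_triplet_counts(self, name, expected):
        k, n_triplets = expected
        sel = ss.selected_atoms(name)
        assert sel.n_atoms == k
        assert sel.n_triplets == n_triplets

    def test_tyr_selection_is_the_seven_named_atoms(self):
        assert ss.selected_atoms("TYR").atoms == ("N", "CA", "CB", "CG", "OH", "C", "O")

    def test_all_standard_residues_have_selections(self):
        for name in STANDARD_RESIDUES:
            sel = ss.selected_atoms(name)
            assert sel.n_atoms >= 3
            k = sel.n_atoms
            assert sel.n_triplets == k * (k - 1) * (k - 2) // 6

    def test_unknown_residue_is_named_in_the_error(self):
        with pytest.raises(KeyError, match="XYZ"):
            ss.selected_atoms("XYZ")

    def test_duplicate_atoms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ss.ResidueSelection("FAKE", ("N", "CA", "N"))

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ss.ResidueSelection("FAKE", ("N", "CA"))


class TestEnumerateTriplets:
    @pytest.mark.parametrize(
        "k,expected", [(3, 1), (5, 10), (7, 35), (12, 220)]
    )
    def test_count_is_k_choose_3(self, k, expected):
        sel = ss.ResidueSelection("FAKE", tuple(f"A{i}" for i in range(k)))
        assert len(ss.enumerate_triplets(sel)) == expected

    def test_vertex_is_middle_atom_in_topological_order(self):
        triplets = ss.enumerate_triplets(ss.selected_atoms("ALA"))
        order = {a: i for i, a in enumerate(ss.selected_atoms("ALA").atoms)}
        for t in triplets:
            ia, iv, ib = order[t.atom_a], order[t.vertex], order[t.atom_b]
            assert ia < iv < ib

    def test_output_order_deterministic_and_unique(self):
        sel = ss.selected_atoms("ARG")
        a = [t.label for t in ss.enumerate_triplets(sel)]
        b = [t.label for t in ss.enumerate_triplets(sel)]
        assert a == b
        assert len(set(a)) == len(a)


class TestAngle:
    def test_equilateral_triangle(self):
        p = [(0, 0, 0), (1, 0, 0), (0.5, math.sqrt(3) / 2, 0)]
        assert ss.angle(p[1], p[0], p[2]) == pytest.approx(math.pi / 3, abs=1e-12)

    def test_collinear_with_vertex_between(self):
        assert ss.angle((-1, 0, 0), (0, 0, 0), (2, 0, 0)) == pytest.approx(math.pi)

    def test_zero_length_arm_errors(self):
        with pytest.raises(ValueError, match="zero length"):
            ss.angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_against_law_of_cosines_oracle(self, rng):
        """1000 random coordinate triples vs an oracle built from the
        three pairwise distances alone."""
        for _ in range(1000):
            a, v, b = rng.normal(size=(3, 3))
            dav = np.linalg.norm(a - v)
            dbv = np.linalg.norm(b - v)
            dab = np.linalg.norm(a - b)
            cos_th = (dav**2 + dbv**2 - dab**2) / (2 * dav * dbv)
            oracle = math.acos(max(-1.0, min(1.0, cos_th)))
            assert abs(ss.angle(a, v, b) - oracle) < 1e-9

    def test_rigid_motion_and_scale_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        pts = rng.normal(size=(3, 3))
        base = ss.angle(*pts)
        for _ in range(20):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(size=3)
            s = float(rng.uniform(0.1, 10))
            moved = [s * (R @ p) + t for p in pts]
            assert abs(ss.angle(*moved) - base) < 1e-9

    def test_symmetric_in_arm_order(self, rng):
        a, v, b = rng.normal(size=(3, 3))
        assert ss.angle(a, v, b) == pytest.approx(ss.angle(b, v, a), abs=1e-15)


class TestAngleSeries:
    def test_recovers_prescribed_schedule(self, toy_system, toy_trajectories):
        trip = ss.AtomTriplet(1, *toy_system.designated_triplet)
        series = ss.angle_series(toy_trajectories, 1, trip)
        truth = toy_system.truth[1].series.values
        assert np.abs(series.values - truth).max() < 1e-6

    def test_segments_record_trajectory_boundaries(self, toy_trajectories):
        trip = ss.AtomTriplet(1, "N", "CA", "O")
        series = ss.angle_series(toy_trajectories, 1, trip)
        assert series.segments == [(0, 500), (500, 1000)]

    def test_missing_atom_named_in_error(self, toy_trajectories):
        trip = ss.AtomTriplet(1, "N", "CA", "OXT")
        with pytest.raises(KeyError, match="OXT"):
            ss.angle_series(toy_trajectories, 1, trip)

    def test_missing_residue_errors(self, toy_trajectories):
        with pytest.raises(KeyError, match="99"):
            ss.angle_series(toy_trajectories, 99, ss.AtomTriplet(99, "N", "CA", "O"))


def _make_trajset(xyz):
    return TrajectorySet(topology=None, xyz=np.asarray(xyz, float),
                         segments=[(0, len(xyz))])


class TestRmsd:
    def test_zero_against_itself_and_rigid_copies(self, rng):
        from scipy.spatial.transform import Rotation

        frame = rng.normal(size=(12, 3))
        R = Rotation.random(rng=rng).as_matrix()
        moved = frame @ R.T + rng.normal(size=3)
        ts = _make_trajset([frame, frame.copy(), moved])
        r = ss.rmsd_series(ts, reference_frame_index=0)
        assert r[0] == pytest.approx(0.0, abs=1e-12)
        assert r[1] == pytest.approx(0.0, abs=1e-9)
        assert r[2] == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_closed_form(self, rng):
        """n-1 identical atoms pin the superposition; displacing one atom
        by d gives RMSD d*sqrt(n-1)/n (≈ d/sqrt(n))."""
        n, d = 100, 0.01
        frame = rng.normal(scale=5.0, size=(n, 3))
        moved = frame.copy()
        # displace radially (away from the centroid) so the optimal rotation
        # cannot absorb any of the displacement to first order
        radial = frame[0] - frame.mean(axis=0)
        moved[0] += d * radial / np.linalg.norm(radial)
        ts = _make_trajset([frame, moved])
        r = ss.rmsd_series(ts, reference_frame_index=0)
        expected = d * math.sqrt(n - 1) / n
        assert r[1] == pytest.approx(expected, rel=1e-3)
        assert r[1] == pytest.approx(d / math.sqrt(n), rel=0.02)

    def test_non_negative(self, rng):
        ts = _make_trajset(rng.normal(size=(5, 8, 3)))
        assert (ss.rmsd_series(ts, 0) >= 0).all()

    def test_empty_subset_rejected(self, rng):
        ts = _make_trajset(rng.normal(size=(2, 4, 3)))
        with pytest.raises(ValueError, match="non-empty"):
            ss.rmsd_series(ts, 0, atom_indices=[])

    def test_bad_subset_rejected(self, rng):
        ts = _make_trajset(rng.normal(size=(2, 4, 3)))
        with pytest.raises(IndexError):
            ss.rmsd_series(ts, 0, atom_indices=[99])


class TestPairDistance:
    def test_three_four_five(self, toy_trajectories):
        # distances computed on explicit coordinates
        xyz = np.zeros((1, 2, 3))
        xyz[0, 1] = (3.0, 4.0, 0.0)
        ts = _make_trajset(xyz)
        d = np.linalg.norm(xyz[:, 0] - xyz[:, 1], axis=1)
        assert d[0] == pytest.approx(5.0)

    def test_scripted_separation_recovered(self, toy_system, toy_trajectories):
        # CA atoms of toy residues sit 0.6 nm apart along z by construction
        d = ss.pair_distance_series(toy_trajectories, 1, 2, "CA")
        assert np.abs(d - 0.6).max() < 1e-6

    def test_missing_atom_errors(self, toy_trajectories):
        with pytest.raises(KeyError, match="CZ"):
            ss.pair_distance_series(toy_trajectories, 1, 2, "CZ")
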