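import numpy as np
import pytest

from unfoldmap import (
    HBondCriteria,
    HBondSetDef,
    Trajectory,
    TripletDef,
    count_hbonds_series,
    count_waters_near,
    detect_hbonds,
    make_hbond_fixture,
    make_solvation_fixture,
    moving_average,
    triplet_angle_series,
)
from unfoldmap.model import Atom, Topology
from conftest import random_rotation


def brute_force_hbonds(traj, frame, criteria):
    """Independent oracle: exhaustive O(D*H*A) triple scan."""
    top = traj.topology
    x = traj.coords[frame]
    heavy_no = [
        i for i in range(top.n_atoms)
        if not top.is_hydrogen[i] and not top.is_water[i] and top.elements[i] in ("N", "O")
    ]
    hydrogens = [i for i in range(top.n_atoms) if top.is_hydrogen[i] and not top.is_water[i]]
    found = set()
    for d in heavy_no:
        for h in hydrogens:
            if np.linalg.norm(x[d] - x[h]) >= 1.2:
                continue
            for a in heavy_no:
                if a == d or top.residue_index[a] == top.residue_index[d]:
                    continue
                if np.linalg.norm(x[d] - x[a]) > criteria.da_cutoff_A:
                    continue
                v1, v2 = x[d] - x[h], x[a] - x[h]
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if ang >= 180 - criteria.angle_tolerance_deg:
                    found.add((d, h, a))
    return found


class TestHBondCriteria:
    @pytest.mark.parametrize(
        "da,angle,expected",
        [
            (2.9, 180.0, 1),  # collinear within cutoff
            (3.6, 180.0, 0),  # beyond distance cutoff
            (2.9, 120.0, 0),  # 60 deg deviation beyond tolerance
            (3.5, 135.0, 1),  # both criteria exactly at the boundary
        ],
    )
    def test_boundary_geometries(self, da, angle, expected):
        traj = make_hbond_fixture(da, angle)
        assert len(detect_hbonds(traj, 0)) == expected

    def test_rigid_transform_invariance(self):
        traj = make_hbond_fixture(3.2, 160.0)
        rng = np.random.default_rng(2)
        for _ in range(10):
            R = random_rotation(rng)
            moved = Trajectory(
                topology=traj.topology, coords=traj.coords @ R.T + rng.normal(size=3)
            )
            assert len(detect_hbonds(moved, 0)) == 1

    def test_no_hydrogens_is_an_error(self):
        atoms = [
            Atom(1, "N", "N", 0, "ALA", 1, "A", False, False),
            Atom(2, "O", "O", 1, "ALA", 2, "A", False, False),
        ]
        traj = Trajectory(topology=Topology(atoms), coords=np.zeros((1, 2, 3)) + [[0, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="no hydrogens"):
            detect_hbonds(traj, 0)

    def test_agrees_with_brute_force_oracle_on_random_frames(self):
        rng = np.random.default_rng(14)
        criteria = HBondCriteria()
        for trial in range(10):
            atoms, coords = [], []
            serial = 0
            for r in range(12):
                for name, el in (("N", "N"), ("H", "H"), ("O", "O"), ("C", "C")):
                    serial += 1
                    atoms.append(Atom(serial, name, el, r, "ALA", r + 1, "A", False, el == "H"))
            coords = rng.uniform(0, 12, size=(1, len(atoms), 3))
            # Drop hydrogens near their donors so some attachments exist.
            for k, a in enumerate(atoms):
                if a.is_hydrogen:
                    coords[0, k] = coords[0, k - 1] + rng.normal(0, 0.5, 3)
            traj = Trajectory(topology=Topology(atoms), coords=coords)
            got = {(b.donor, b.hydrogen, b.acceptor) for b in detect_hbonds(traj, 0, criteria)}
            assert got == brute_force_hbonds(traj, 0, criteria)


class TestHBondSets:
    def test_bond_counted_in_spanning_set_only(self):
        # Two bonds spanning (1-2)<->(3-5); a third residue pair inside (1-2).
        base = make_hbond_fixture(2.9, 180.0)
        sets = [
            HBondSetDef("span", (1, 2), (3, 5)),
            HBondSetDef("inside", (1, 1), (2, 2)),
        ]
        # Fixture residues are 1 (donor) and 2 (acceptor).
        counts = count_hbonds_series(base, sets)
        assert counts["span"].tolist() == [0]
        assert counts["inside"].tolist() == [1]

    def test_orientation_agnostic_membership(self):
        s = HBondSetDef("s", (3, 12), (15, 25))
        assert s.contains(5, 20) and s.contains(20, 5)
        assert not s.contains(5, 7)

    def test_static_frames_give_constant_counts(self):
        one = make_hbond_fixture(2.9, 180.0)
        multi = Trajectory(topology=one.topology, coords=np.repeat(one.coords, 3, axis=0))
        counts = count_hbonds_series(multi, [HBondSetDef("s", (1, 1), (2, 2))])
        assert counts["s"].tolist() == [1, 1, 1]


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(moving_average([3.0] * 20, 11), 3.0)

    def test_interior_impulse_spreads_over_window(self):
        x = np.zeros(31)
        x[15] = 11.0
        out = moving_average(x, 11)
        np.testing.assert_allclose(out[10:21], 1.0)
        assert out[9] == 0.0 and out[21] == 0.0

    def test_edge_uses_shrinking_window(self):
        x = np.arange(20.0)
        out = moving_average(x, 11)
        assert out[0] == pytest.approx(np.mean(x[:6]))
        assert len(out) == len(x)

    def test_output_bounded_by_input_range(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        out = moving_average(x, 11)
        assert out.min() >= x.min() - 1e-12 and out.max() <= x.max() + 1e-12

    @pytest.mark.parametrize("window", [2, 0, -3])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError, match="odd"):
            moving_average([1.0, 2.0], window)


class TestWaterShell:
    def test_recovers_planted_schedule(self):
        schedule = [5, 3, 0, 7]
        traj = make_solvation_fixture(schedule, radius_A=4.0, seed=12)
        per_res, aggregate = count_waters_near(traj, [1], radius_A=4.0)
        assert aggregate.tolist() == schedule
        assert per_res[1].tolist() == schedule

    def test_radius_controls_count(self):
        atoms = [
            Atom(1, "CA", "C", 0, "ALA", 1, "A", False, False),
            Atom(2, "OH2", "O", 1, "HOH", 100, "W", True, False),
        ]
        coords = np.array([[[0, 0, 0], [3.0, 0, 0]]])
        traj = Trajectory(topology=Topology(atoms), coords=coords)
        assert count_waters_near(traj, [1], 4.0)[1].tolist() == [1]
        assert count_waters_near(traj, [1], 2.5)[1].tolist() == [0]

    def test_aggregate_deduplicates_shared_waters(self):
        atoms = [
            Atom(1, "CA", "C", 0, "ALA", 15, "A", False, False),
            Atom(2, "CA", "C", 1, "ALA", 16, "A", False, False),
            Atom(3, "OH2", "O", 2, "HOH", 100, "W", True, False),
        ]
        coords = np.array([[[0, 0, 0], [2.0, 0, 0], [1.0, 0, 0]]])
        traj = Trajectory(topology=Topology(atoms), coords=coords)
        per_res, aggregate = count_waters_near(traj, [15, 16], 4.0)
        assert per_res[15].tolist() == [1] and per_res[16].tolist() == [1]
        assert aggregate.tolist() == [1]

    def test_no_waters_is_an_error(self):
        atoms = [Atom(1, "CA", "C", 0, "ALA", 1, "A", False, False)]
        traj = Trajectory(topology=Topology(atoms), coords=np.zeros((1, 1, 3)))
        with pytest.raises(ValueError, match="no water"):
            count_waters_near(traj, [1], 4.0)


def _ca_triplet_traj(points):
    atoms = [Atom(i + 1, "CA", "C", i, "ALA", i + 1, "A", False, False) for i in range(3)]
    return Trajectory(topology=Topology(atoms), coords=np.array([points]))


class TestTripletAngles:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([[-1, 0, 0], [0, 0, 0], [1, 0, 0]], 180.0),
            ([[1, 0, 0], [0, 0, 0], [0, 1, 0]], 90.0),
            ([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]], 60.0),
        ],
    )
    def test_elementary_geometries(self, points, expected):
        traj = _ca_triplet_traj(points)
        angles = triplet_angle_series(traj, [TripletDef((1, 2, 3))])
        assert angles[(1, 2, 3)][0] == pytest.approx(expected)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(8)
        points = rng.normal(size=(3, 3))
        base = triplet_angle_series(_ca_triplet_traj(points), [TripletDef((1, 2, 3))])[(1, 2, 3)]
        for _ in range(5):
            R = random_rotation(rng)
            moved = triplet_angle_series(
                _ca_triplet_traj(points @ R.T + rng.normal(size=3)), [TripletDef((1, 2, 3))]
            )[(1, 2, 3)]
            np.testing.assert_allclose(moved, base, atol=1e-8)

    def test_degenerate_geometry_names_frame(self):
        traj = _ca_triplet_traj([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="frame 0"):
            triplet_angle_series(traj, [TripletDef((1, 2, 3))])

    def test_duplicate_residues_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            TripletDef((1, 1, 2))
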