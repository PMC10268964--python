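import numpy as np
import pytest

from memtraj.core import Topology, Trajectory
from memtraj.interactions import (
    HBondCriterion,
    contact_count_series,
    detect_hbonds,
    distance_below_fraction,
    occupancy,
)
from memtraj.synthetic import HBondFixture, generate_study, receptor_spec

from conftest import ca_topology


def hbond_topology(n_donors, n_acceptors):
    """Donor residues carry N + H; acceptor residues carry a lone O."""
    names, elements, resids, resnames, chains = [], [], [], [], []
    for i in range(n_donors):
        names += ["N", "H"]
        elements += ["N", "H"]
        resids += [i + 1, i + 1]
        resnames += ["DON", "DON"]
        chains += ["D", "D"]
    for i in range(n_acceptors):
        names.append("O")
        elements.append("O")
        resids.append(i + 1)
        resnames.append("ACC")
        chains.append("A")
    return Topology(names, elements, resids, resnames, chains)


def brute_force_hbonds(coords, donors, dh, acceptors, crit):
    found = set()
    for d in donors:
        for a in acceptors:
            if np.linalg.norm(coords[a] - coords[d]) > crit.distance_cutoff:
                continue
            for h in dh[int(d)]:
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
                if ang >= crit.angle_cutoff:
                    found.add((int(d), int(h), int(a)))
    return found


class TestDetectHbonds:
    @pytest.mark.parametrize("dist,ang,present", [
        (2.8, 170.0, True),   # inside both cutoffs
        (3.2, 170.0, False),  # distance fails
        (2.8, 120.0, False),  # angle fails
    ])
    def test_cutoff_classification(self, dist, ang, present):
        spec = receptor_spec(
            seed=0, frames=4, sigma=0.0, membrane=False,
            residues={k: 3 for k in ("IC_A", "TM_A", "EC_A", "TM_B", "EC_B", "LIG")},
            hbond_fixtures=[HBondFixture(distance=dist, angle_deg=ang)])
        topo, _, traj, _ = generate_study(spec)
        bonds = detect_hbonds(traj, topo, topo.select(names=["DN"]),
                              topo.select(names=["AO"]))
        assert all(bool(frame) == present for frame in bonds)

    def test_matches_brute_force_scan(self, rng):
        topo = hbond_topology(12, 15)
        donors = topo.select(names=["N"])
        acceptors = topo.select(names=["O"])
        coords = np.empty((50, topo.n_atoms, 3))
        coords[:, donors, :] = rng.uniform(0, 12, size=(50, 12, 3))
        # hydrogens 1 A from their donor in a random direction
        u = rng.normal(size=(50, 12, 3))
        u /= np.linalg.norm(u, axis=2, keepdims=True)
        coords[:, donors + 1, :] = coords[:, donors, :] + u
        coords[:, acceptors, :] = rng.uniform(0, 12, size=(50, 15, 3))
        traj = Trajectory(coords)
        crit = HBondCriterion(3.0, 135.0)
        result = detect_hbonds(traj, topo, donors, acceptors, crit)
        from memtraj.interactions import find_donor_hydrogens
        dh = find_donor_hydrogens(topo, coords[0], donors)
        for f in range(50):
            got = {(b.donor, b.hydrogen, b.acceptor) for b in result[f]}
            assert got == brute_force_hbonds(coords[f], donors, dh,
                                             acceptors, crit)

    def test_donor_without_hydrogen_rejected(self, rng):
        topo = ca_topology(3)  # no hydrogens at all
        traj = Trajectory(rng.normal(size=(2, 3, 3)))
        with pytest.raises(ValueError, match="no attached hydrogen"):
            detect_hbonds(traj, topo, np.array([0]), np.array([2]))


class TestOccupancy:
    @pytest.fixture(scope="class")
    def toggling_bonds(self):
        spec = receptor_spec(
            seed=0, frames=100, sigma=0.0, membrane=False,
            residues={k: 3 for k in ("IC_A", "TM_A", "EC_A", "TM_B", "EC_B", "LIG")},
            hbond_fixtures=[HBondFixture(distance=2.8, angle_deg=170.0, period=2)])
        topo, _, traj, _ = generate_study(spec)
        donors = topo.select(names=["DN"])
        acceptors = topo.select(names=["AO"])
        bonds = detect_hbonds(traj, topo, donors, acceptors)
        return topo, donors, acceptors, bonds

    def test_even_frame_schedule_is_50_percent(self, toggling_bonds):
        topo, donors, acceptors, bonds = toggling_bonds
        rec = occupancy(bonds, int(donors[0]), int(acceptors[0]))
        assert rec.occupancy == 50.0
        assert rec.frames_present == 50

    def test_57_of_100(self, toggling_bonds):
        _, donors, acceptors, bonds = toggling_bonds
        # keep the bond in exactly 57 of 100 frames
        on_frame = bonds[0]
        trimmed = [on_frame if i < 57 else [] for i in range(100)]
        rec = occupancy(trimmed, int(donors[0]), int(acceptors[0]))
        assert rec.occupancy == pytest.approx(57.0)

    def test_never_bonded_valid_pair_is_zero(self, toggling_bonds):
        _, donors, acceptors, bonds = toggling_bonds
        empty = [[] for _ in bonds]
        rec = occupancy(empty, int(donors[0]), int(acceptors[0]),
                        donors=donors, acceptors=acceptors)
        assert rec.occupancy == 0.0

    def test_unknown_pair_rejected(self, toggling_bonds):
        _, donors, acceptors, bonds = toggling_bonds
        with pytest.raises(KeyError, match="unknown pair"):
            occupancy(bonds, 999998, 999999)

    def test_occupancy_monotone_as_cutoffs_tighten(self, rng):
        topo = hbond_topology(6, 6)
        donors = topo.select(names=["N"])
        acceptors = topo.select(names=["O"])
        coords = np.empty((40, topo.n_atoms, 3))
        coords[:, donors, :] = rng.uniform(0, 8, size=(40, 6, 3))
        u = rng.normal(size=(40, 6, 3))
        u /= np.linalg.norm(u, axis=2, keepdims=True)
        coords[:, donors + 1, :] = coords[:, donors, :] + u
        coords[:, acceptors, :] = rng.uniform(0, 8, size=(40, 6, 3))
        traj = Trajectory(coords)
        prev = None
        for dist, ang in [(3.5, 120.0), (3.0, 135.0), (2.8, 150.0)]:
            bonds = detect_hbonds(traj, topo, donors, acceptors,
                                  HBondCriterion(dist, ang))
            total = sum(len(f) for f in bonds)
            if prev is not None:
                assert total <= prev
            prev = total


class TestDistanceBelowFraction:
    def _pair_traj(self, distances):
        topo = ca_topology(2)
        coords = np.zeros((len(distances), 2, 3))
        coords[:, 1, 0] = distances
        return topo, Trajectory(coords)

    def test_always_below(self):
        topo, traj = self._pair_traj([3.5] * 10)
        assert distance_below_fraction(traj, topo, np.array([0]),
                                       np.array([1]), 4.0) == 100.0

    def test_never_below(self):
        topo, traj = self._pair_traj([5.0] * 10)
        assert distance_below_fraction(traj, topo, np.array([0]),
                                       np.array([1]), 4.0) == 0.0

    def test_577_of_1000(self):
        d = np.full(1000, 5.0)
        d[:577] = 3.5
        topo, traj = self._pair_traj(d)
        out = distance_below_fraction(traj, topo, np.array([0]),
                                      np.array([1]), 4.0)
        assert out == pytest.approx(57.7)

    def test_com_mode_differs_from_min_mode(self):
        # closest atoms touch while the centers of mass stay far apart
        topo = ca_topology(4)
        coords = np.array([[[0.0, 0, 0], [0, 0, 10], [3, 0, 0], [30, 0, 0]]])
        a, b = np.array([0, 1]), np.array([2, 3])
        traj = Trajectory(coords)
        assert distance_below_fraction(traj, topo, a, b, 4.0, "min") == 100.0
        assert distance_below_fraction(traj, topo, a, b, 4.0, "com") == 0.0


class TestContactCounts:
    def test_single_pair_within_cutoff(self):
        topo = ca_topology(2)
        coords = np.array([[[0.0, 0, 0], [3, 0, 0]]])
        out = contact_count_series(Trajectory(coords), topo,
                                   np.array([0]), np.array([1]), 4.5)
        assert out.counts.tolist() == [1]

    def test_minimum_image_across_boundary(self):
        topo = ca_topology(2)
        coords = np.array([[[1.0, 1, 1], [19.0, 1, 1]]])
        box = np.array([[20.0, 20.0, 20.0]])
        with_pbc = contact_count_series(Trajectory(coords, box=box), topo,
                                        np.array([0]), np.array([1]), 4.5)
        without = contact_count_series(Trajectory(coords), topo,
                                       np.array([0]), np.array([1]), 4.5)
        assert with_pbc.counts[0] == 1  # images 2 A apart
        assert without.counts[0] == 0

    def test_matches_brute_force_with_pbc(self, rng):
        n = 200
        topo = ca_topology(2 * n)
        box_l = 30.0
        coords = rng.uniform(0, box_l, size=(50, 2 * n, 3))
        box = np.full((50, 3), box_l)
        a, b = np.arange(n), np.arange(n, 2 * n)
        out = contact_count_series(Trajectory(coords, box=box), topo, a, b, 6.0)
        for f in range(0, 50, 7):
            diff = coords[f, a][:, None, :] - coords[f, b][None, :, :]
            diff -= box_l * np.round(diff / box_l)
            d = np.sqrt((diff**2).sum(-1))
            assert out.counts[f] == int((d <= 6.0).sum())

    def test_overlapping_selections_rejected(self, rng):
        topo = ca_topology(4)
        traj = Trajectory(rng.normal(size=(2, 4, 3)))
        with pytest.raises(ValueError, match="disjoint"):
            contact_count_series(traj, topo, np.array([0, 1]), np.array([1, 2]))

    def test_cutoff_above_half_box_rejected(self):
        topo = ca_topology(2)
        traj = Trajectory(np.zeros((1, 2, 3)), box=np.array([[8.0, 8.0, 8.0]]))
        with pytest.raises(ValueError, match="half"):
            contact_count_series(traj, topo, np.array([0]), np.array([1]), 4.5)
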