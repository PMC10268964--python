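import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtraj.core import Trajectory
from memtraj.geometry import (
    AngleSeries,
    VectorSpec,
    angle_occupancy_map,
    axis_angle_series,
    com,
    com_distance_series,
    com_series,
    crossing_angle_series,
)

from conftest import ca_topology, static_trajectory


def vector_system(v, n_frames=1):
    """Two single-atom 'domains' defining the vector v = head - tail."""
    topo = ca_topology(2)
    coords = np.zeros((n_frames, 2, 3))
    coords[:, 1, :] = v
    spec = VectorSpec.between({"resid_range": (1, 1)}, {"resid_range": (2, 2)})
    return topo, Trajectory(coords), spec


def helix_pair(direction_b, n_res=5):
    """Two straight C-alpha 'helices': A along +z, B along ``direction_b``."""
    topo = ca_topology(2 * n_res)
    # residues 1..5 chain A-range, 6..10 second helix (same chain id)
    coords = np.zeros((1, 2 * n_res, 3))
    for i in range(n_res):
        coords[0, i] = [0, 0, 1.5 * i]
        coords[0, n_res + i] = np.asarray([5.0, 0, 0]) + 1.5 * i * np.asarray(direction_b)
    return topo, Trajectory(coords)


class TestCom:
    def test_unit_masses_midpoint(self):
        assert np.allclose(com(np.array([[0.0, 0, 0], [4, 0, 0]])), [2, 0, 0])

    def test_weighted(self):
        out = com(np.array([[0.0, 0, 0], [4, 0, 0]]), np.array([1.0, 3.0]))
        assert out[0] == pytest.approx(3.0)

    def test_matches_brute_force(self, rng):
        topo = ca_topology(50)
        coords = rng.normal(size=(3, 50, 3))
        out = com_series(Trajectory(coords), topo, np.arange(50))
        m = topo.masses
        for f in range(3):
            expected = sum(m[i] * coords[f, i] for i in range(50)) / m.sum()
            assert np.allclose(out[f], expected, atol=1e-12)

    def test_empty_selection_rejected(self, rng):
        topo = ca_topology(3)
        traj = Trajectory(rng.normal(size=(2, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            com_series(traj, topo, np.array([], dtype=int))


class TestAxisAngle:
    @pytest.mark.parametrize("v,axis,expected", [
        ((0, 0, 5), "z", 0.0),
        ((3, 0, 0), "z", 90.0),
        ((1, 0, 1), "z", 45.0),
        ((0, 2, 0), "y", 0.0),
        ((0, 0, -1), "z", 180.0),
    ])
    def test_closed_forms(self, v, axis, expected):
        topo, traj, spec = vector_system(v)
        out = axis_angle_series(traj, topo, spec, axis=axis)
        assert out.values[0] == pytest.approx(expected, abs=1e-9)

    def test_antipodal_vectors_sum_to_180(self, rng):
        v = rng.normal(size=3)
        topo, traj, spec = vector_system(v)
        a = axis_angle_series(traj, topo, spec, "z").values[0]
        topo2, traj2, spec2 = vector_system(-v)
        b = axis_angle_series(traj2, topo2, spec2, "z").values[0]
        assert a + b == pytest.approx(180.0, abs=1e-9)

    def test_scale_invariance(self, rng):
        v = rng.normal(size=3)
        for scale in (1.0, 17.0):
            topo, traj, spec = vector_system(scale * v)
            out = axis_angle_series(traj, topo, spec, "x")
            if scale == 1.0:
                base = out.values[0]
        assert out.values[0] == pytest.approx(base, abs=1e-9)

    def test_degenerate_vector_names_frame(self):
        topo, traj, spec = vector_system((0.0, 0, 0), n_frames=3)
        with pytest.raises(ValueError, match="frame 0"):
            axis_angle_series(traj, topo, spec, "z")


class TestCrossingAngle:
    def test_parallel_helices_zero(self):
        topo, traj = helix_pair((0, 0, 1.0))
        out = crossing_angle_series(traj, topo, ("A", 1, 5), ("A", 6, 10))
        assert out.values[0] == pytest.approx(0.0, abs=1e-6)

    def test_antiparallel_helices_180(self):
        topo, traj = helix_pair((0, 0, -1.0))
        out = crossing_angle_series(traj, topo, ("A", 1, 5), ("A", 6, 10))
        assert out.values[0] == pytest.approx(180.0, abs=1e-6)

    def test_symmetric_in_helices(self):
        topo, traj = helix_pair((0.3, 0.1, 0.9))
        a = crossing_angle_series(traj, topo, ("A", 1, 5), ("A", 6, 10))
        b = crossing_angle_series(traj, topo, ("A", 6, 10), ("A", 1, 5))
        assert a.values[0] == pytest.approx(b.values[0], abs=1e-12)

    def test_scheduled_tilt_recovered(self):
        from memtraj.synthetic import RigidMotion, generate_study, receptor_spec
        spec = receptor_spec(
            seed=51, frames=100, sigma=0.0, membrane=False,
            rigid_motions=[RigidMotion("TM_B", axis="x", amplitude_deg=25.0,
                                       schedule="step", onset=0.5)],
        )
        topo, part, traj, _ = generate_study(spec)
        tm_a = next(d for d in part.domains if d.name == "TM_A")
        tm_b = next(d for d in part.domains if d.name == "TM_B")
        base = crossing_angle_series(
            traj, topo, ("A", tm_a.first, tm_a.last), ("B", tm_b.first, tm_b.last))
        first, second = base.values[:50], base.values[50:]
        assert np.allclose(second - first, 25.0, atol=0.5)

    def test_missing_calpha_rejected(self):
        topo, traj = helix_pair((0, 0, 1.0))
        with pytest.raises(ValueError, match="C-alpha"):
            crossing_angle_series(traj, topo, ("A", 1, 5), ("B", 6, 10))


class TestComDistance:
    def test_pythagorean(self):
        topo = ca_topology(2)
        coords = np.array([[[0.0, 0, 0], [3, 4, 0]]])
        out = com_distance_series(Trajectory(coords), topo,
                                  np.array([0]), np.array([1]))
        assert out[0] == pytest.approx(5.0)

    def test_identical_selections_zero(self, rng):
        topo = ca_topology(4)
        traj = Trajectory(rng.normal(size=(3, 4, 3)))
        sel = np.arange(4)
        assert np.allclose(com_distance_series(traj, topo, sel, sel), 0.0)

    def test_constant_fixture_exact(self):
        topo = ca_topology(2)
        coords = np.zeros((20, 2, 3))
        coords[:, 1, 0] = 10.6
        out = com_distance_series(Trajectory(coords), topo,
                                  np.array([0]), np.array([1]))
        assert out.mean() == pytest.approx(10.6, abs=1e-12)


class TestAngleOccupancyMap:
    def test_constant_series_single_bin(self):
        a = AngleSeries(np.full(100, 40.0))
        b = AngleSeries(np.full(100, 70.0))
        counts, edges = angle_occupancy_map(a, b, bin_width=10.0)
        assert counts.sum() == 100
        assert counts.max() == 100
        assert counts[4, 7] == 100  # bins [40,50) x [70,80)

    def test_counts_conserved_for_random_series(self, rng):
        a = AngleSeries(rng.uniform(0, 180, 500))
        b = AngleSeries(rng.uniform(0, 180, 500))
        counts, _ = angle_occupancy_map(a, b, bin_width=10.0)
        assert counts.sum() == 500

    def test_uniform_series_pass_chi2(self):
        from scipy.stats import chi2
        reject = 0
        n, bins = 6480, 18  # 20 frames per 10-degree bin expected
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            counts, _ = angle_occupancy_map(
                AngleSeries(r.uniform(0, 180, n)),
                AngleSeries(r.uniform(0, 180, n)), bin_width=10.0)
            expected = n / bins**2
            stat = ((counts - expected) ** 2 / expected).sum()
            if stat > chi2.ppf(0.99, bins**2 - 1):
                reject += 1
        assert reject <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            angle_occupancy_map(AngleSeries(np.zeros(3)),
                                AngleSeries(np.zeros(4)), 10.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=3, max_size=3).filter(
    lambda v: np.linalg.norm(v) > 1e-3))
def test_axis_angle_always_in_range(v):
    topo, traj, spec = vector_system(tuple(v))
    out = axis_angle_series(traj, topo, spec, "z")
    assert 0.0 <= out.values[0] <= 180.0
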