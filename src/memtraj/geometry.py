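"""Vector and angle protocols: domain tilt against the cell vertical,
transmembrane helix crossing angles, and center-of-mass distance series.

Angles are reported in degrees on [0, 180] without folding to [0, 90], so
that crossed vs splayed ("Y"-shaped) helix arrangements and tilts past 90
degrees remain distinguishable. A helix axis is the vector from the first
to the last C-alpha of the stated residue range, the literal end-to-end
protocol; a least-squares fitted axis is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Topology, Trajectory

__all__ = [
    "VectorSpec",
    "AngleSeries",
    "com",
    "com_series",
    "axis_angle_series",
    "crossing_angle_series",
    "com_distance_series",
    "angle_occupancy_map",
]

_AXES = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]),
         "z": np.array([0, 0, 1.0])}


@dataclass(frozen=True)
class VectorSpec:
    """A per-frame vector from the COM of ``tail`` to the COM of ``head``."""

    tail: tuple  # selection keyword dict items, hashable
    head: tuple
    mass_weighted: bool = True
    label: str = ""

    @staticmethod
    def between(tail: dict, head: dict, mass_weighted: bool = True,
                label: str = "") -> "VectorSpec":
        return VectorSpec(tuple(sorted(tail.items())),
                          tuple(sorted(head.items())), mass_weighted, label)

    def resolve(self, topology: Topology) -> tuple[np.ndarray, np.ndarray]:
        tail = topology.select(**dict(self.tail))
        head = topology.select(**dict(self.head))
        if tail.size == 0 or head.size == 0:
            raise ValueError(f"vector spec {self.label!r}: empty selection")
        if np.intersect1d(tail, head).size:
            raise ValueError(f"vector spec {self.label!r}: selections overlap")
        return tail, head


@dataclass
class AngleSeries:
    values: np.ndarray  # degrees in [0, 180]
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.size and (v.min() < -1e-9 or v.max() > 180 + 1e-9):
            raise ValueError("angles must lie in [0, 180] degrees")
        self.values = np.clip(v, 0.0, 180.0)


def com(coords: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """(Weighted) centroid of one frame's coordinates, shape (3,)."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape[0] == 0:
        raise ValueError("empty selection has no center of mass")
    if masses is None:
        return coords.mean(axis=0)
    m = np.asarray(masses, dtype=np.float64)
    return (m[:, None] * coords).sum(axis=0) / m.sum()


def com_series(
    traj: Trajectory,
    topology: Topology,
    selection: np.ndarray,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame center of mass (Angstrom), shape (frames, 3)."""
    selection = np.asarray(selection, dtype=np.int64)
    if selection.size == 0:
        raise ValueError("empty selection has no center of mass")
    x = traj.coords[:, selection, :]
    if not mass_weighted:
        return x.mean(axis=1)
    m = topology.masses[selection]
    return (x * m[None, :, None]).sum(axis=1) / m.sum()


def _angle_deg(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    nv = np.linalg.norm(v, axis=-1)
    nw = np.linalg.norm(w, axis=-1)
    bad = np.flatnonzero((nv < 1e-6) | (nw < 1e-6))
    if bad.size:
        raise ValueError(f"degenerate (near-zero) vector at frame {int(bad[0])}")
    cosang = np.einsum("...k,...k->...", v, w) / (nv * nw)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def axis_angle_series(
    traj: Trajectory,
    topology: Topology,
    vec: VectorSpec,
    axis: str = "z",
) -> AngleSeries:
    """Angle (degrees) of a COM-difference vector against a unit-cell axis."""
    if axis not in _AXES:
        raise ValueError("axis must be one of 'x', 'y', 'z'")
    tail, head = vec.resolve(topology)
    v = (com_series(traj, topology, head, vec.mass_weighted)
         - com_series(traj, topology, tail, vec.mass_weighted))
    a = np.broadcast_to(_AXES[axis], v.shape)
    return AngleSeries(_angle_deg(v, a), vec.label or f"angle-vs-{axis}")


def _helix_axis(traj, topology, chain, first, last, fitted=False) -> np.ndarray:
    lo, hi = sorted((int(first), int(last)))
    ca = topology.select(names=["CA"], chains=[chain], resid_range=(lo, hi))
    if ca.size < 2:
        raise ValueError(
            f"helix {chain}:{lo}-{hi} needs >= 2 C-alpha atoms, found {ca.size}"
        )
    x = traj.coords[:, ca, :]
    if not fitted:
        return x[:, -1, :] - x[:, 0, :]
    # least-squares axis: dominant right singular vector of the centered stack,
    # oriented from the first to the last residue
    axes = np.empty((traj.n_frames, 3))
    for f in range(traj.n_frames):
        c = x[f] - x[f].mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        ax = vt[0]
        if ax @ (x[f, -1] - x[f, 0]) < 0:
            ax = -ax
        axes[f] = ax
    return axes


def crossing_angle_series(
    traj: Trajectory,
    topology: Topology,
    helix_a: tuple[str, int, int],
    helix_b: tuple[str, int, int],
    fitted_axis: bool = False,
) -> AngleSeries:
    """Angle between the end-to-end C-alpha axes of two helices, per frame.

    Each helix is (chain, first residue, last residue); endpoints unordered.
    """
    va = _helix_axis(traj, topology, *helix_a, fitted=fitted_axis)
    vb = _helix_axis(traj, topology, *helix_b, fitted=fitted_axis)
    return AngleSeries(_angle_deg(va, vb), "crossing-angle")


def com_distance_series(
    traj: Trajectory,
    topology: Topology,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame distance (Angstrom) between two selections' centers of mass.

    Single-atom selections reduce to the plain atom-atom distance.
    """
    ca = com_series(traj, topology, sel_a, mass_weighted)
    cb = com_series(traj, topology, sel_b, mass_weighted)
    return np.linalg.norm(ca - cb, axis=1)


def angle_occupancy_map(
    a: AngleSeries,
    b: AngleSeries,
    bin_width: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint histogram of two angle series over [0, 180]^2.

    Returns (counts, bin_edges); counts sum to the frame count.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("angle series lengths differ")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    if edges[-1] < 180.0:
        edges = np.append(edges, 180.0)
    counts, _, _ = np.histogram2d(a.values, b.values, bins=[edges, edges])
    return counts, edges
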