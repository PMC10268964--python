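"""Geometric hydrogen-bond detection, occupancy statistics and contact counts.

A hydrogen bond is recorded in a frame when the donor-heavy-atom to
acceptor distance is at most the distance cutoff (default 3.0 Angstrom)
AND the donor-H-acceptor angle at the hydrogen is at least the angle
cutoff (default 135 degrees; larger angles are more linear). Occupancy is
the percentage of analyzed frames in which a given triplet satisfies both
criteria. Contact counting uses the minimum-image convention whenever the
trajectory carries box lengths; the default heavy-atom contact cutoff is
4.5 Angstrom and is stamped into every output table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Topology, Trajectory

__all__ = [
    "HBondCriterion",
    "HBond",
    "OccupancyRecord",
    "ContactSeries",
    "find_donor_hydrogens",
    "detect_hbonds",
    "occupancy",
    "occupancy_table",
    "distance_below_fraction",
    "contact_count_series",
    "DEFAULT_CONTACT_CUTOFF",
]

DEFAULT_CONTACT_CUTOFF = 4.5  # Angstrom, heavy-atom convention


@dataclass(frozen=True)
class HBondCriterion:
    distance_cutoff: float = 3.0  # donor-acceptor, Angstrom
    angle_cutoff: float = 135.0   # D-H...A at the hydrogen, degrees, lower bound

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0 < self.angle_cutoff <= 180):
            raise ValueError("angle cutoff must lie in (0, 180]")


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float
    angle: float


@dataclass
class OccupancyRecord:
    donor: int
    hydrogen: int
    acceptor: int
    frames_present: int
    frames_total: int

    @property
    def occupancy(self) -> float:
        return 100.0 * self.frames_present / self.frames_total


@dataclass
class ContactSeries:
    counts: np.ndarray  # per-frame integer pair counts
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"frame": np.arange(self.counts.size),
                           "contacts": self.counts})
        df.attrs["cutoff_A"] = self.cutoff
        return df


def find_donor_hydrogens(
    topology: Topology,
    coords: np.ndarray,
    donors: np.ndarray,
    max_bond: float = 1.2,
) -> dict[int, list[int]]:
    """Hydrogens covalently attached to each donor heavy atom.

    Attachment is name convention (element H in the same residue) confirmed
    by a distance below ``max_bond`` in the supplied frame. A donor with no
    attached hydrogen raises.
    """
    out: dict[int, list[int]] = {}
    hydrogens = np.flatnonzero(
        np.fromiter((str(e).strip().upper() in ("H", "D") for e in topology.elements),
                    bool, topology.n_atoms)
    )
    for d in np.asarray(donors, dtype=np.int64):
        same_res = hydrogens[topology.atom_residue[hydrogens] == topology.atom_residue[d]]
        if same_res.size:
            dist = np.linalg.norm(coords[same_res] - coords[d], axis=1)
            attached = same_res[dist < max_bond].tolist()
        else:
            attached = []
        if not attached:
            raise ValueError(
                f"donor atom {int(d)} ({topology.names[d]} in "
                f"{topology.residue_label(int(topology.atom_residue[d]))}) "
                "has no attached hydrogen"
            )
        out[int(d)] = attached
    return out


def _dha_angle(coords, d, h, a) -> float:
    v1 = coords[d] - coords[h]
    v2 = coords[a] - coords[h]
    c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_hbonds(
    traj: Trajectory,
    topology: Topology,
    donors: np.ndarray,
    acceptors: np.ndarray,
    criterion: HBondCriterion = HBondCriterion(),
) -> list[list[HBond]]:
    """Per-frame hydrogen-bond lists between donor and acceptor selections."""
    donors = np.asarray(donors, dtype=np.int64)
    acceptors = np.asarray(acceptors, dtype=np.int64)
    if donors.size == 0 or acceptors.size == 0:
        raise ValueError("donor and acceptor selections must be non-empty")
    dh = find_donor_hydrogens(topology, traj.coords[0], donors)
    frames: list[list[HBond]] = []
    for f in range(traj.n_frames):
        coords = traj.coords[f]
        tree = cKDTree(coords[acceptors])
        bonds: list[HBond] = []
        for d in donors:
            near = tree.query_ball_point(coords[d], criterion.distance_cutoff)
            for k in near:
                a = int(acceptors[k])
                if a == int(d):
                    continue
                dist = float(np.linalg.norm(coords[a] - coords[d]))
                for h in dh[int(d)]:
                    ang = _dha_angle(coords, int(d), h, a)
                    if ang >= criterion.angle_cutoff:
                        bonds.append(HBond(int(d), h, a, dist, ang))
        frames.append(bonds)
    return frames


def occupancy(
    bond_lists: list[list[HBond]],
    donor: int,
    acceptor: int,
    hydrogen: int | None = None,
    donors: np.ndarray | None = None,
    acceptors: np.ndarray | None = None,
) -> OccupancyRecord:
    """Occupancy of one donor-acceptor pair (optionally a specific hydrogen).

    A pair that never bonds is 0% if it can be validated against the donor
    and acceptor selections used for detection; otherwise it is unknown and
    raises.
    """
    if not bond_lists:
        raise ValueError("no frames analyzed")
    known = {(b.donor, b.acceptor) for frame in bond_lists for b in frame}
    if (donor, acceptor) not in known:
        valid = (
            donors is not None and acceptors is not None
            and donor in np.asarray(donors) and acceptor in np.asarray(acceptors)
        )
        if not valid:
            raise KeyError(
                f"unknown pair ({donor}, {acceptor}): never bonded and not "
                "part of the donor/acceptor selections"
            )
    present = 0
    h_seen = hydrogen
    for frame in bond_lists:
        hit = [b for b in frame if b.donor == donor and b.acceptor == acceptor
               and (hydrogen is None or b.hydrogen == hydrogen)]
        if hit:
            present += 1
            h_seen = hit[0].hydrogen
    return OccupancyRecord(donor, h_seen if h_seen is not None else -1,
                           acceptor, present, len(bond_lists))


def occupancy_table(bond_lists: list[list[HBond]], topology: Topology) -> pd.DataFrame:
    """Occupancy summary over every donor-acceptor pair ever observed."""
    pairs = sorted({(b.donor, b.acceptor) for frame in bond_lists for b in frame})
    rows = []
    for d, a in pairs:
        rec = occupancy(bond_lists, d, a)
        rows.append({
            "donor": topology.residue_label(int(topology.atom_residue[d]))
                     + ":" + str(topology.names[d]),
            "acceptor": topology.residue_label(int(topology.atom_residue[a]))
                        + ":" + str(topology.names[a]),
            "frames_present": rec.frames_present,
            "frames_total": rec.frames_total,
            "occupancy_pct": rec.occupancy,
        })
    return pd.DataFrame(rows, columns=["donor", "acceptor", "frames_present",
                                       "frames_total", "occupancy_pct"])


def distance_below_fraction(
    traj: Trajectory,
    topology: Topology,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    threshold: float,
    mode: str = "min",
) -> float:
    """Percentage of frames with the A-B distance below ``threshold``.

    ``mode='min'`` uses the minimum atom-pair distance (terminal-atom
    reading); ``mode='com'`` uses the distance between centers of mass.
    """
    sel_a = np.asarray(sel_a, dtype=np.int64)
    sel_b = np.asarray(sel_b, dtype=np.int64)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("selections must be non-empty")
    if mode == "com":
        from .geometry import com_distance_series
        d = com_distance_series(traj, topology, sel_a, sel_b)
    elif mode == "min":
        xa = traj.coords[:, sel_a, :]
        xb = traj.coords[:, sel_b, :]
        diff = xa[:, :, None, :] - xb[:, None, :, :]
        d = np.sqrt((diff**2).sum(-1)).reshape(traj.n_frames, -1).min(axis=1)
    else:
        raise ValueError("mode must be 'min' or 'com'")
    return 100.0 * float(np.count_nonzero(d < threshold)) / traj.n_frames


def contact_count_series(
    traj: Trajectory,
    topology: Topology,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactSeries:
    """Per-frame count of A-B atom pairs within ``cutoff`` Angstrom.

    Uses the minimum-image convention when the trajectory has a box (the
    cutoff must then be below half the smallest box edge). Selections must
    be disjoint.
    """
    sel_a = np.asarray(sel_a, dtype=np.int64)
    sel_b = np.asarray(sel_b, dtype=np.int64)
    if np.intersect1d(sel_a, sel_b).size:
        raise ValueError("contact selections must be disjoint")
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("selections must be non-empty")
    counts = np.empty(traj.n_frames, dtype=np.int64)
    for f in range(traj.n_frames):
        coords = traj.coords[f]
        if traj.box is not None:
            box = traj.box[f]
            if cutoff >= box.min() / 2:
                raise ValueError("cutoff must be below half the smallest box edge")
            xa = np.mod(coords[sel_a], box)
            xb = np.mod(coords[sel_b], box)
            ta = cKDTree(xa, boxsize=box)
            tb = cKDTree(xb, boxsize=box)
        else:
            ta = cKDTree(coords[sel_a])
            tb = cKDTree(coords[sel_b])
        counts[f] = int(ta.count_neighbors(tb, cutoff))
    return ContactSeries(counts, cutoff)
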