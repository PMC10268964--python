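"""Core data model: topology, trajectory, domain partitions and frame selection.

Coordinates are always stored in Angstrom, regardless of the on-disk format.
Only orthorhombic periodic boxes are supported; analyses that need periodicity
receive per-frame box edge lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ATOMIC_MASSES",
    "Topology",
    "Trajectory",
    "DomainPartition",
    "Domain",
    "FrameSelection",
    "select_frames",
    "wrap_frames",
]

# Standard atomic weights (amu), IUPAC 2021 abridged values.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "He": 4.003,
    "Li": 6.94, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06,
    "Cl": 35.45, "K": 39.098, "Ca": 40.078, "Mn": 54.938, "Fe": 55.845,
    "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38, "Se": 78.971,
    "Br": 79.904, "I": 126.904,
}


class TopologyError(ValueError):
    pass


class TrajectoryError(ValueError):
    pass


class Topology:
    """Atoms grouped into residues and chains.

    Parameters are parallel per-atom arrays. Residues are identified by
    (chain id, residue sequence number) in order of first appearance;
    residue numbering is taken as printed (1-based in PDB convention).
    """

    def __init__(
        self,
        names: Sequence[str],
        elements: Sequence[str],
        resids: Sequence[int],
        resnames: Sequence[str],
        chainids: Sequence[str],
        masses: Sequence[float] | None = None,
    ) -> None:
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.resids = np.asarray(resids, dtype=np.int64)
        self.resnames = np.asarray(resnames, dtype=object)
        self.chainids = np.asarray(chainids, dtype=object)
        n = len(self.names)
        if not (len(self.elements) == len(self.resids) == len(self.resnames)
                == len(self.chainids) == n):
            raise TopologyError("per-atom arrays must have equal length")
        if n == 0:
            raise TopologyError("topology contains zero atoms")

        if masses is None:
            masses = []
            for i, el in enumerate(self.elements):
                key = str(el).strip().capitalize()
                if key not in ATOMIC_MASSES:
                    raise TopologyError(
                        f"unknown element {el!r} for atom index {i} "
                        f"({self.names[i]} in residue {self.resnames[i]} {self.resids[i]})"
                    )
                masses.append(ATOMIC_MASSES[key])
        self.masses = np.asarray(masses, dtype=np.float64)
        if np.any(self.masses <= 0):
            raise TopologyError("all atomic masses must be strictly positive")

        # residue table keyed by (chain, resid) in order of first appearance
        keys = list(zip(self.chainids, self.resids))
        seen: dict[tuple, int] = {}
        atom_residue = np.empty(n, dtype=np.int64)
        res_chain: list[str] = []
        res_seq: list[int] = []
        res_name: list[str] = []
        for i, key in enumerate(keys):
            if key not in seen:
                seen[key] = len(res_chain)
                res_chain.append(key[0])
                res_seq.append(int(key[1]))
                res_name.append(self.resnames[i])
            atom_residue[i] = seen[key]
        self.atom_residue = atom_residue
        self.residue_chain = np.asarray(res_chain, dtype=object)
        self.residue_seq = np.asarray(res_seq, dtype=np.int64)
        self.residue_name = np.asarray(res_name, dtype=object)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_seq)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for c in self.chainids:
            if c not in out:
                out.append(c)
        return out

    def residue_label(self, ridx: int) -> str:
        return f"{self.residue_chain[ridx]}:{self.residue_name[ridx]}{self.residue_seq[ridx]}"

    def select(
        self,
        names: Iterable[str] | None = None,
        chains: Iterable[str] | None = None,
        resid_range: tuple[int, int] | None = None,
        residues: Iterable[int] | None = None,
        resnames: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Atom indices matching all given criteria.

        ``resid_range`` endpoints are inclusive and unordered (normalized).
        ``residues`` are global residue indices (rows of the residue table).
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        if names is not None:
            nameset = set(names)
            mask &= np.fromiter((n in nameset for n in self.names), bool, self.n_atoms)
        if chains is not None:
            chainset = set(chains)
            mask &= np.fromiter((c in chainset for c in self.chainids), bool, self.n_atoms)
        if resnames is not None:
            rset = set(resnames)
            mask &= np.fromiter((r in rset for r in self.resnames), bool, self.n_atoms)
        if resid_range is not None:
            lo, hi = sorted(int(x) for x in resid_range)
            mask &= (self.resids >= lo) & (self.resids <= hi)
        if residues is not None:
            rset = set(int(r) for r in residues)
            mask &= np.fromiter((int(r) in rset for r in self.atom_residue), bool, self.n_atoms)
        return np.flatnonzero(mask)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<Topology {self.n_atoms} atoms, {self.n_residues} residues, "
                f"{len(self.chains)} chains>")


class Trajectory:
    """Per-frame coordinates (Angstrom) plus orthorhombic box edge lengths."""

    def __init__(
        self,
        coords: np.ndarray,
        box: np.ndarray | None = None,
        time: np.ndarray | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise TrajectoryError("coordinates must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise TrajectoryError("coordinates contain non-finite values")
        self.coords = coords
        if box is not None:
            box = np.asarray(box, dtype=np.float64)
            if box.ndim == 1:
                box = np.tile(box, (coords.shape[0], 1))
            if box.shape != (coords.shape[0], 3):
                raise TrajectoryError("box must have shape (frames, 3)")
            if np.any(box <= 0):
                raise TrajectoryError("box edge lengths must be strictly positive")
        self.box = box
        if time is not None:
            time = np.asarray(time, dtype=np.float64)
            if time.shape != (coords.shape[0],):
                raise TrajectoryError("time must have one entry per frame")
        self.time = time

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def check_atoms(self, topology: Topology) -> None:
        if self.n_atoms != topology.n_atoms:
            raise TrajectoryError(
                f"trajectory has {self.n_atoms} atoms but topology has {topology.n_atoms}"
            )

    def __getitem__(self, frames) -> "Trajectory":
        idx = np.arange(self.n_frames)[frames]
        return Trajectory(
            self.coords[idx],
            None if self.box is None else self.box[idx],
            None if self.time is None else self.time[idx],
        )


@dataclass(frozen=True)
class Domain:
    name: str
    chain: str
    first: int
    last: int

    def __post_init__(self):
        if self.last < self.first:
            # unordered endpoints are normalized
            lo, hi = self.last, self.first
            object.__setattr__(self, "first", lo)
            object.__setattr__(self, "last", hi)


@dataclass
class DomainPartition:
    """Named domains mapped to chain + inclusive residue ranges."""

    domains: list[Domain] = field(default_factory=list)

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[str, str, int, int]]) -> "DomainPartition":
        doms = []
        for name, chain, first, last in entries:
            lo, hi = sorted((int(first), int(last)))
            doms.append(Domain(str(name), str(chain), lo, hi))
        part = cls(doms)
        part._validate()
        return part

    def _validate(self) -> None:
        names = [d.name for d in self.domains]
        if len(set(names)) != len(names):
            raise TopologyError("domain names must be unique")
        by_chain: dict[str, list[Domain]] = {}
        for d in self.domains:
            by_chain.setdefault(d.chain, []).append(d)
        for chain, doms in by_chain.items():
            spans = sorted((d.first, d.last, d.name) for d in doms)
            for (a0, a1, an), (b0, b1, bn) in zip(spans, spans[1:]):
                if b0 <= a1:
                    raise TopologyError(
                        f"domains {an!r} and {bn!r} overlap on chain {chain}"
                    )

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.domains]

    def residue_indices(self, topology: Topology) -> dict[str, np.ndarray]:
        """Global residue indices per domain; deterministic, order independent."""
        out: dict[str, np.ndarray] = {}
        for d in self.domains:
            mask = (
                (topology.residue_chain == d.chain)
                & (topology.residue_seq >= d.first)
                & (topology.residue_seq <= d.last)
            )
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                raise TopologyError(
                    f"domain {d.name!r} (chain {d.chain} {d.first}-{d.last}) "
                    "resolves to no residue in the topology"
                )
            out[d.name] = idx
        return out

    def atom_indices(self, topology: Topology, names: Iterable[str] | None = None
                     ) -> dict[str, np.ndarray]:
        res = self.residue_indices(topology)
        return {
            dom: topology.select(names=names, residues=ridx)
            for dom, ridx in res.items()
        }


@dataclass(frozen=True)
class FrameSelection:
    """Fractional window [start, end) of the trajectory plus a stride.

    The default keeps the second half of the frames (equilibration excluded)
    at stride 1.
    """

    start: float = 0.5
    end: float = 1.0
    stride: int = 1

    def __post_init__(self):
        if not (0.0 <= self.start < 1.0):
            raise ValueError("start fraction must lie in [0, 1)")
        if not (0.0 < self.end <= 1.0):
            raise ValueError("end fraction must lie in (0, 1]")
        if self.start >= self.end:
            raise ValueError("start fraction must be below end fraction")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    def frame_indices(self, n_frames: int) -> np.ndarray:
        first = int(np.floor(self.start * n_frames))
        stop = int(np.ceil(self.end * n_frames))
        return np.arange(first, stop, self.stride, dtype=np.int64)


def wrap_frames(traj: Trajectory) -> Trajectory:
    """Imaging pre-pass: wrap every atom into the primary cell [0, L).

    Requires per-frame box lengths. Analyses that assume a whole molecule
    should not be run on wrapped coordinates; this exists for periodic
    neighbour searches.
    """
    if traj.box is None:
        raise TrajectoryError("wrapping requires box lengths")
    wrapped = np.mod(traj.coords, traj.box[:, None, :])
    return Trajectory(wrapped, traj.box.copy(),
                      None if traj.time is None else traj.time.copy())


def select_frames(traj: Trajectory, sel: FrameSelection) -> Trajectory:
    """Contiguous strided frame subset; timestamps preserved."""
    idx = sel.frame_indices(traj.n_frames)
    if idx.size < 2:
        raise TrajectoryError(
            f"frame selection yields {idx.size} frame(s); "
            "statistical analyses need at least 2"
        )
    return traj[idx]
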