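"""Readers and writers for PDB, DCD and XTC, plus the domain-partition file.

PDB text is parsed here (fixed columns) so that malformed records can be
reported with their line number. Binary trajectory formats go through
MDAnalysis; XTC coordinates arrive already converted from nm to Angstrom.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import yaml

from .core import (
    ATOMIC_MASSES,
    DomainPartition,
    Topology,
    Trajectory,
    TrajectoryError,
)

__all__ = [
    "read_topology",
    "read_trajectory",
    "write_pdb",
    "write_trajectory",
    "read_partition",
    "write_partition",
]


class PDBParseError(ValueError):
    pass


def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "_"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 77 else ""
    if not element:
        # fall back on the first alphabetic character of the atom name
        stripped = name.lstrip("0123456789")
        element = stripped[:1]
    return name, resname, chain, resid, (x, y, z), element


def _parse_cryst1(line: str, lineno: int) -> np.ndarray:
    try:
        a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
        al, be, ga = float(line[33:40]), float(line[40:47]), float(line[47:54])
    except ValueError as exc:
        raise PDBParseError(f"malformed CRYST1 record at line {lineno}") from exc
    if not np.allclose([al, be, ga], 90.0, atol=1e-3):
        raise TrajectoryError(
            "triclinic boxes are not supported (only orthorhombic cells)"
        )
    return np.array([a, b, c], dtype=np.float64)


def _read_pdb(path: str):
    """All models of a PDB file: (atom fields, frames, boxes)."""
    names, resnames, chains, resids, elements = [], [], [], [], []
    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    box = None
    first_model_done = False
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                box = _parse_cryst1(line, lineno)
            elif rec == "MODEL":
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                if frames and len(current) != len(frames[0]):
                    raise TrajectoryError(
                        f"truncated frame {len(frames)} in {path}: "
                        f"{len(current)} atoms, expected {len(frames[0])}"
                    )
                frames.append(current)
                first_model_done = True
                current = []
            elif rec in ("ATOM", "HETATM"):
                name, resname, chain, resid, xyz, element = _parse_atom_line(line, lineno)
                if not first_model_done:
                    names.append(name)
                    resnames.append(resname)
                    chains.append(chain)
                    resids.append(resid)
                    elements.append(element)
                current.append(xyz)
            elif rec == "END" and current and not in_model:
                frames.append(current)
                first_model_done = True
                current = []
    if current:
        if frames and len(current) != len(frames[0]):
            raise TrajectoryError(
                f"truncated frame {len(frames)} in {path}: "
                f"{len(current)} atoms, expected {len(frames[0])}"
            )
        frames.append(current)
    return (names, elements, resids, resnames, chains), frames, box


def read_topology(path: str) -> Topology:
    """Topology from the first model of a PDB file.

    Masses are assigned from the element (standard atomic weights); an
    unrecognized element raises.
    """
    fields, frames, _ = _read_pdb(path)
    names, elements, resids, resnames, chains = fields
    if not names:
        raise PDBParseError(f"{path} contains no ATOM/HETATM records")
    return Topology(names, elements, resids, resnames, chains)


def read_trajectory(path: str, topology: Topology) -> Trajectory:
    """Trajectory from a multi-model PDB, DCD or XTC file (frames in order)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".pdb", ".ent"):
        _, frames, box = _read_pdb(path)
        if not frames:
            raise TrajectoryError(f"{path} contains no coordinate frames")
        coords = np.asarray(frames, dtype=np.float64)
        if coords.shape[1] != topology.n_atoms:
            raise TrajectoryError(
                f"{path} has {coords.shape[1]} atoms per frame, "
                f"topology has {topology.n_atoms}"
            )
        return Trajectory(coords, box=box)
    if ext == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDReader
        reader = DCDReader(path)
    elif ext == ".xtc":
        from MDAnalysis.coordinates.XTC import XTCReader
        reader = XTCReader(path)
    else:
        raise TrajectoryError(f"unsupported trajectory format: {ext!r}")
    if reader.n_atoms != topology.n_atoms:
        raise TrajectoryError(
            f"{path} has {reader.n_atoms} atoms, topology has {topology.n_atoms}"
        )
    coords, boxes, times = [], [], []
    for ts in reader:
        coords.append(ts.positions.astype(np.float64).copy())
        if ts.dimensions is not None and ts.dimensions[:3].any():
            dims = ts.dimensions
            if not np.allclose(dims[3:], 90.0, atol=1e-3):
                raise TrajectoryError(
                    "triclinic boxes are not supported (only orthorhombic cells)"
                )
            boxes.append(np.asarray(dims[:3], dtype=np.float64))
        times.append(float(ts.time) / 1000.0)  # ps -> ns
    reader.close()
    box = np.asarray(boxes) if len(boxes) == len(coords) else None
    return Trajectory(np.asarray(coords), box=box, time=np.asarray(times))


def write_pdb(
    path: str,
    topology: Topology,
    traj: Trajectory | np.ndarray,
    bfactors: np.ndarray | None = None,
) -> None:
    """Write a (multi-model) PDB; optional per-atom B-factor column."""
    coords = traj.coords if isinstance(traj, Trajectory) else np.asarray(traj, float)
    if coords.ndim == 2:
        coords = coords[None]
    box = traj.box if isinstance(traj, Trajectory) else None
    b = np.zeros(topology.n_atoms) if bfactors is None else np.asarray(bfactors, float)
    with open(path, "w") as fh:
        if box is not None:
            a, c, d = box[0]
            fh.write(f"CRYST1{a:9.3f}{c:9.3f}{d:9.3f}  90.00  90.00  90.00 P 1           1\n")
        multi = coords.shape[0] > 1
        for m in range(coords.shape[0]):
            if multi:
                fh.write(f"MODEL     {m + 1:4d}\n")
            for i in range(topology.n_atoms):
                name = topology.names[i]
                pname = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
                x, y, z = coords[m, i]
                fh.write(
                    f"ATOM  {i + 1 if i < 99999 else 99999:5d} {pname}"
                    f"{'':1s}{topology.resnames[i]:<3s} {topology.chainids[i][:1]}"
                    f"{int(topology.resids[i]) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b[i]:6.2f}"
                    f"          {str(topology.elements[i]).rjust(2)[:2]}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_trajectory(path: str, topology: Topology, traj: Trajectory) -> None:
    """Write a trajectory as multi-model PDB, DCD or XTC (by extension)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".pdb", ".ent"):
        write_pdb(path, topology, traj)
        return
    if ext not in (".dcd", ".xtc"):
        raise TrajectoryError(f"unsupported trajectory format: {ext!r}")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    if traj.box is not None:
        dims = np.hstack([traj.box, np.full((traj.n_frames, 3), 90.0)])
    else:
        dims = None
    u.load_new(
        traj.coords.astype(np.float32),
        format=MemoryReader,
        dimensions=dims,
    )
    with mda.Writer(path, n_atoms=topology.n_atoms) as w:
        for ts in u.trajectory:
            w.write(u.atoms)


def read_partition(path: str) -> DomainPartition:
    """Domain partition from a YAML/JSON file.

    Accepts either a list of mappings with keys name/chain/first/last or a
    mapping ``{domains: [...]}``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict) and "domains" in data:
        data = data["domains"]
    if not isinstance(data, list):
        raise ValueError(f"{path}: expected a list of domain entries")
    entries = []
    for item in data:
        try:
            entries.append((item["name"], str(item["chain"]),
                            int(item["first"]), int(item["last"])))
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: bad domain entry {item!r}: {exc}") from exc
    return DomainPartition.from_entries(entries)


def write_partition(path: str, partition: DomainPartition) -> None:
    data = {
        "domains": [
            {"name": d.name, "chain": d.chain, "first": int(d.first), "last": int(d.last)}
            for d in partition.domains
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
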