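"""Essential dynamics: mass-weighted covariance PCA of a trajectory.

Frames are superposed onto the first frame (the production-run starting
configuration) to remove rigid-body motion; the covariance of the
mass-weighted coordinates sqrt(m_i) x_i is then diagonalized. Eigenvalues
carry units of Angstrom^2 amu and are sorted descending; the low-index
eigenvectors are the dominant collective motions. Projections of the
mass-weighted displacements onto an eigenvector have variance equal to its
eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Topology, Trajectory
from .fitting import align_frames

__all__ = ["EigenSystem", "ModeProjection", "pca", "project", "mode_arrows"]


@dataclass
class EigenSystem:
    eigenvalues: np.ndarray        # (3N,), descending, Angstrom^2 amu
    eigenvectors: np.ndarray       # (3N, 3N), orthonormal columns
    selection: np.ndarray          # atom indices the modes live on
    masses: np.ndarray             # (N,), amu
    mean: np.ndarray               # (3N,) mass-weighted mean coordinates
    reference: np.ndarray          # (N, 3) fit reference (first frame)
    trace: float                   # trace of the covariance

    @property
    def variance_fraction(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues * 0.0

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_fraction)


@dataclass
class ModeProjection:
    pc_index: int
    values: np.ndarray               # per-frame projection, Angstrom sqrt(amu)
    cumulative_variance: np.ndarray  # per PC, fraction of total


def _weighted_centered(traj: Trajectory, eig_or_sel, masses) -> np.ndarray:
    x = traj.coords[:, eig_or_sel, :]
    w = np.sqrt(masses)[None, :, None]
    y = (x * w).reshape(traj.n_frames, -1)
    return y


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude component positive."""
    out = vecs.copy()
    for k in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, k])))
        if out[i, k] < 0:
            out[:, k] = -out[:, k]
    return out


def pca(
    traj: Trajectory,
    topology: Topology,
    selection: np.ndarray | None = None,
    mass_weighted: bool = True,
    fit: bool = True,
) -> EigenSystem:
    """Eigendecomposition of the mass-weighted positional covariance.

    The fit reference is the first frame. With ``mass_weighted=False`` unit
    weights are used (the same code path serves e.g. lipid-phosphorus
    selections with uniform weighting).
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    traj.check_atoms(topology)
    if selection is None:
        selection = topology.select(names=["CA"])
    selection = np.asarray(selection, dtype=np.int64)
    if selection.size < 2:
        raise ValueError("PCA needs at least 2 atoms")
    masses = topology.masses[selection] if mass_weighted else np.ones(selection.size)

    work = align_frames(traj, traj.coords[0, selection], selection) if fit else traj
    y = _weighted_centered(work, selection, masses)
    mean = y.mean(axis=0)
    yc = y - mean
    cov = yc.T @ yc / yc.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = _fix_signs(evecs[:, order])
    # zero out the numerically negative tail of the spectrum
    tiny = np.abs(evals) < 1e-12 * max(1.0, float(evals.max(initial=0.0)))
    evals[tiny & (evals < 0)] = 0.0
    return EigenSystem(
        eigenvalues=evals,
        eigenvectors=evecs,
        selection=selection,
        masses=masses,
        mean=mean,
        reference=traj.coords[0, selection].copy(),
        trace=float(np.trace(cov)),
    )


def project(traj: Trajectory, eig: EigenSystem, pc_index: int,
            fit: bool = True) -> ModeProjection:
    """Per-frame projection of the mass-weighted displacements onto one PC."""
    if not (0 <= pc_index < eig.eigenvectors.shape[1]):
        raise IndexError(f"pc_index {pc_index} out of range")
    work = align_frames(traj, eig.reference, eig.selection) if fit else traj
    y = _weighted_centered(work, eig.selection, eig.masses)
    vals = (y - eig.mean) @ eig.eigenvectors[:, pc_index]
    return ModeProjection(pc_index, vals, eig.cumulative_variance)


def mode_arrows(eig: EigenSystem, pc_index: int, scale: float = 1.0) -> np.ndarray:
    """Per-atom real-space displacement vectors of one mode.

    The eigenvector lives in mass-weighted coordinates; the back-transform
    divides each atom's components by sqrt(m), so arrow lengths are
    proportional to the atom's eigenvector amplitude over sqrt(mass).
    """
    if not (0 <= pc_index < eig.eigenvectors.shape[1]):
        raise IndexError(f"pc_index {pc_index} out of range")
    v = eig.eigenvectors[:, pc_index].reshape(-1, 3)
    return scale * v / np.sqrt(eig.masses)[:, None]


def write_mode_pdb(path: str, topology: Topology, eig: EigenSystem,
                   pc_index: int, scale: float = 1.0) -> None:
    """Two-model PDB (base + displaced) visualizing one mode's arrows."""
    from .io import write_pdb

    arrows = mode_arrows(eig, pc_index, scale)
    base = eig.reference
    coords = np.stack([base, base + arrows])
    sub = Topology(
        topology.names[eig.selection], topology.elements[eig.selection],
        topology.resids[eig.selection], topology.resnames[eig.selection],
        topology.chainids[eig.selection], topology.masses[eig.selection],
    )
    write_pdb(path, sub, coords)
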