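"""Least-squares superposition and RMSD / RMSF / B-factor analyses.

The superposition is the weighted Kabsch problem: the proper rotation R and
translation t minimizing sum_i w_i |R x_i + t - y_i|^2. RMSF is computed
against the time-averaged structure obtained from a two-pass alignment
(align to the first frame, average, re-align to the average), the standard
resolution when the reference is "an averaged structure from the run".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Topology, Trajectory

__all__ = [
    "SuperpositionResult",
    "FluctuationProfile",
    "kabsch_fit",
    "apply_fit",
    "align_frames",
    "rmsd_series",
    "average_structure",
    "rmsf_profile",
    "BFACTOR_PER_MSF",
]

# B = (8 pi^2 / 3) <u^2>
BFACTOR_PER_MSF = 8.0 * np.pi**2 / 3.0


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,), Angstrom
    rmsd: float  # Angstrom, weighted

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class FluctuationProfile:
    residue_labels: list[str]
    rmsf: np.ndarray  # (n_residues,), Angstrom
    bfactor: np.ndarray  # (n_residues,), Angstrom^2


def kabsch_fit(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Weighted least-squares superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (reflections rejected), the translation and
    the weighted RMSD after the fit. Needs >= 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    mob_c = (w[:, None] * mobile).sum(0) / wsum
    ref_c = (w[:, None] * reference).sum(0) / wsum
    a = mobile - mob_c
    b = reference - ref_c
    # degenerate (collinear / coincident) geometry has a rank-deficient
    # cross-covariance and no unique rotation
    cov = (w[:, None] * b).T @ a
    if np.linalg.matrix_rank(cov, tol=1e-10 * max(1.0, np.abs(cov).max())) < 2:
        raise ValueError("degenerate geometry: superposition is not unique")
    rot, rssd = Rotation.align_vectors(b, a, weights=w)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    rmsd = float(rssd / np.sqrt(wsum))
    return SuperpositionResult(R, t, rmsd)


def apply_fit(coords: np.ndarray, fit: SuperpositionResult) -> np.ndarray:
    return fit.transform(np.asarray(coords, dtype=np.float64))


def align_frames(
    traj: Trajectory,
    reference: np.ndarray,
    fit_indices: np.ndarray,
    weights: np.ndarray | None = None,
) -> Trajectory:
    """Superpose every frame onto ``reference`` using atoms ``fit_indices``.

    ``reference`` holds coordinates of the fit atoms only; the returned
    trajectory has all atoms transformed by each frame's fit.
    """
    fit_indices = np.asarray(fit_indices, dtype=np.int64)
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        fit = kabsch_fit(traj.coords[f, fit_indices], reference, weights)
        out[f] = fit.transform(traj.coords[f])
    return Trajectory(out, traj.box, traj.time)


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    selection: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) after fitting each frame on ``selection``.

    ``reference`` is the full-atom reference structure; fitting and
    reporting use the same selection.
    """
    selection = np.asarray(selection, dtype=np.int64)
    if selection.size == 0:
        raise ValueError("empty selection")
    reference = np.asarray(reference, dtype=np.float64)
    ref_sel = reference[selection]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = kabsch_fit(traj.coords[f, selection], ref_sel, weights).rmsd
    return out


def average_structure(
    traj: Trajectory,
    fit_indices: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Time-averaged structure after aligning all frames to frame 0."""
    aligned = align_frames(traj, traj.coords[0, fit_indices], fit_indices, weights)
    return aligned.coords.mean(axis=0)


def rmsf_profile(
    traj: Trajectory,
    topology: Topology,
    align_selection: np.ndarray,
    report_selection: np.ndarray | None = None,
    mass_weighted_fit: bool = False,
) -> FluctuationProfile:
    """Per-residue RMSF and B-factor about the time-averaged structure.

    The alignment selection (e.g. receptor only) and the reporting selection
    (default: all C-alpha atoms) are independent. Two passes: frames are
    aligned to frame 0, averaged, then re-aligned to that average before the
    fluctuations are accumulated. B = (8 pi^2 / 3) RMSF^2.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    align_selection = np.asarray(align_selection, dtype=np.int64)
    if align_selection.size == 0:
        raise ValueError("empty alignment selection")
    if report_selection is None:
        report_selection = topology.select(names=["CA"])
    report_selection = np.asarray(report_selection, dtype=np.int64)
    if report_selection.size == 0:
        raise ValueError("empty reporting selection")

    weights = topology.masses[align_selection] if mass_weighted_fit else None
    avg = average_structure(traj, align_selection, weights)
    aligned = align_frames(traj, avg[align_selection], align_selection, weights)

    mean = aligned.coords.mean(axis=0)
    msf_atom = ((aligned.coords - mean) ** 2).sum(axis=2).mean(axis=0)

    res_of = topology.atom_residue[report_selection]
    labels: list[str] = []
    rmsf: list[float] = []
    for ridx in sorted(set(int(r) for r in res_of)):
        atoms = report_selection[res_of == ridx]
        labels.append(topology.residue_label(ridx))
        rmsf.append(float(np.sqrt(msf_atom[atoms].mean())))
    rmsf_arr = np.asarray(rmsf)
    return FluctuationProfile(labels, rmsf_arr, BFACTOR_PER_MSF * rmsf_arr**2)
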