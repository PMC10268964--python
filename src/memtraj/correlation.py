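"""Dynamic cross-correlation matrices and domain-pair correlation densities.

The residue-residue correlation is the normalized covariance of C-alpha
displacement vectors,

    CC_ij = <dr_i . dr_j> / sqrt(<dr_i^2> <dr_j^2>),

with dr the displacement from the time mean after the frames have been
superposed onto an averaged reference structure to remove rigid-body motion.
Domain-pair "correlation densities" are signed block means: the sum of
CC_ij over a domain pair divided by the product of the two domains' residue
counts (diagonal blocks include the i = j terms). Differential matrices are
elementwise differences between two models' matrices.

Note on alignment: a displacement field whose pairwise correlations are all
positive necessarily moves its own centroid, and superposition removes
exactly that common mode. When the analysis selection covers the whole
correlated set, self-alignment therefore suppresses the very correlation
being measured; pass an ``align_selection`` anchored on a part of the system
whose motion is independent of the selection of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DomainPartition, Topology, Trajectory
from .fitting import align_frames, average_structure

__all__ = [
    "CorrelationMatrix",
    "DomainMatrix",
    "dccm",
    "domain_matrix",
    "differential_matrix",
]


@dataclass
class CorrelationMatrix:
    """Residue-residue correlation values with their residue index map."""

    residue_indices: np.ndarray  # global residue indices (rows of topology table)
    labels: list[str]
    matrix: np.ndarray
    is_difference: bool = False

    def validate(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not self.is_difference:
            if not np.allclose(np.diag(m), 1.0, atol=1e-10):
                raise ValueError("correlation matrix must have unit diagonal")
            if m.min() < -1 - 1e-9 or m.max() > 1 + 1e-9:
                raise ValueError("correlation values must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass
class DomainMatrix:
    """Domain-pair correlation densities (signed block means)."""

    domain_names: list[str]
    matrix: np.ndarray
    is_difference: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.domain_names,
                            columns=self.domain_names)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.domain_names):
            for j, b in enumerate(self.domain_names):
                rows.append((a, b, self.matrix[i, j]))
        return pd.DataFrame(rows, columns=["domain_a", "domain_b", "density"])


def dccm(
    traj: Trajectory,
    topology: Topology,
    selection: np.ndarray | None = None,
    align_selection: np.ndarray | None = None,
    fit: bool = True,
) -> CorrelationMatrix:
    """Residue cross-correlation matrix on C-alpha atoms.

    Frames are first superposed onto the time-averaged structure computed on
    ``align_selection`` (defaults to the analysis selection); displacements
    are then taken from the per-atom time mean. One atom per residue is
    required in ``selection`` (default: all C-alpha atoms).
    """
    if traj.n_frames < 2:
        raise ValueError("correlation analysis needs at least 2 frames")
    traj.check_atoms(topology)
    if selection is None:
        selection = topology.select(names=["CA"])
    selection = np.asarray(selection, dtype=np.int64)
    res_of = topology.atom_residue[selection]
    if len(set(res_of.tolist())) != selection.size:
        raise ValueError("selection must contain exactly one atom per residue")

    if fit:
        if align_selection is None:
            align_selection = selection
        align_selection = np.asarray(align_selection, dtype=np.int64)
        avg = average_structure(traj, align_selection)
        work = align_frames(traj, avg[align_selection], align_selection)
    else:
        work = traj

    x = work.coords[:, selection, :]  # (F, N, 3)
    disp = x - x.mean(axis=0)
    cov = np.einsum("fik,fjk->ij", disp, disp) / disp.shape[0]
    var = np.diag(cov).copy()
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        names = ", ".join(topology.residue_label(int(res_of[i])) for i in bad[:5])
        raise ValueError(f"zero-variance atom(s) in correlation analysis: {names}")
    norm = np.sqrt(var)
    cc = cov / np.outer(norm, norm)
    # clamp the tiny numerical overshoot of perfectly (anti)correlated pairs
    np.clip(cc, -1.0, 1.0, out=cc)
    cc = (cc + cc.T) / 2.0
    np.fill_diagonal(cc, 1.0)
    labels = [topology.residue_label(int(r)) for r in res_of]
    out = CorrelationMatrix(res_of.copy(), labels, cc)
    out.validate()
    return out


def domain_matrix(ccm: CorrelationMatrix, partition: DomainPartition,
                  topology: Topology) -> DomainMatrix:
    """Aggregate a residue correlation matrix into domain-pair densities.

    entry(P, Q) = sum_{i in P, j in Q} CC_ij / (|P| |Q|); the sums are
    signed and diagonal blocks include the self terms.
    """
    res_to_row = {int(r): k for k, r in enumerate(ccm.residue_indices)}
    dom_res = partition.residue_indices(topology)
    rows_per_domain: dict[str, np.ndarray] = {}
    assigned: set[int] = set()
    for name, ridx in dom_res.items():
        rows = [res_to_row[int(r)] for r in ridx if int(r) in res_to_row]
        rows_per_domain[name] = np.asarray(rows, dtype=np.int64)
        assigned.update(rows)
    missing = [ccm.labels[k] for k in range(len(ccm.labels)) if k not in assigned]
    if missing:
        raise ValueError(
            "residues not assigned to any domain: " + ", ".join(missing[:10])
        )
    names = partition.names
    n = len(names)
    out = np.empty((n, n))
    for i, a in enumerate(names):
        ra = rows_per_domain[a]
        for j, b in enumerate(names):
            rb = rows_per_domain[b]
            if ra.size == 0 or rb.size == 0:
                raise ValueError(f"domain {a if ra.size == 0 else b} has no residues in the matrix")
            out[i, j] = ccm.matrix[np.ix_(ra, rb)].sum() / (ra.size * rb.size)
    out = (out + out.T) / 2.0
    return DomainMatrix(names, out, is_difference=ccm.is_difference)


def differential_matrix(a, b):
    """Elementwise a - b for two same-shaped correlation or domain matrices."""
    if isinstance(a, CorrelationMatrix) and isinstance(b, CorrelationMatrix):
        if (a.residue_indices.shape != b.residue_indices.shape
                or np.any(a.residue_indices != b.residue_indices)):
            raise ValueError("residue maps differ; cannot subtract matrices")
        return CorrelationMatrix(
            a.residue_indices.copy(), list(a.labels),
            a.matrix - b.matrix, is_difference=True,
        )
    if isinstance(a, DomainMatrix) and isinstance(b, DomainMatrix):
        if a.domain_names != b.domain_names:
            raise ValueError("domain name lists differ; cannot subtract matrices")
        return DomainMatrix(list(a.domain_names), a.matrix - b.matrix,
                            is_difference=True)
    raise TypeError("operands must be two CorrelationMatrix or two DomainMatrix objects")
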