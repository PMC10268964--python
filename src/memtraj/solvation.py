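"""Radial distribution functions of a probe selection around tagged atoms.

g(r) is the histogram of center-probe minimum-image distances, each bin
divided by the expected ideal-gas count: exact shell volume
(4 pi / 3)(r2^3 - r1^3) times the probe number density times the number of
center-frame observations. The density is taken from the probe count and
the instantaneous box volume of each frame, so constant-pressure
trajectories with a breathing box are normalized correctly. For a uniform
(ideal-gas) probe fluid g(r) = 1; multiple center atoms are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Topology, Trajectory

__all__ = ["RDFProfile", "rdf"]


@dataclass
class RDFProfile:
    bin_centers: np.ndarray  # Angstrom
    g: np.ndarray            # dimensionless
    density: float           # mean probe number density used, 1/Angstrom^3
    bin_width: float
    r_max: float
    counts: np.ndarray       # raw pair counts per bin

    def cumulative_number(self) -> np.ndarray:
        """n(r): expected number of probes within r of a center."""
        # integrate g * rho * 4 pi r^2 dr using exact shell volumes
        edges = np.concatenate([[self.bin_centers[0] - self.bin_width / 2],
                                self.bin_centers + self.bin_width / 2])
        vol = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
        return np.cumsum(self.g * self.density * vol)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_A": self.bin_centers, "g": self.g})


def _min_image_dist(centers: np.ndarray, probes: np.ndarray,
                    box: np.ndarray | None) -> np.ndarray:
    diff = probes[None, :, :] - centers[:, None, :]
    if box is not None:
        diff -= box * np.round(diff / box)
    return np.sqrt((diff**2).sum(-1))


def rdf(
    traj: Trajectory,
    topology: Topology,
    centers: np.ndarray,
    probes: np.ndarray,
    bin_width: float = 0.1,
    r_max: float = 10.0,
) -> RDFProfile:
    """Radial distribution function g(r) of ``probes`` around ``centers``.

    With a periodic box, ``r_max`` must stay below half the smallest edge so
    every distance has a unique minimum image. Self pairs (an atom in both
    selections) are excluded.
    """
    centers = np.asarray(centers, dtype=np.int64)
    probes = np.asarray(probes, dtype=np.int64)
    if centers.size == 0 or probes.size == 0:
        raise ValueError("center and probe selections must be non-empty")
    if bin_width <= 0 or r_max <= bin_width:
        raise ValueError("need bin_width > 0 and r_max > bin_width")
    if traj.box is not None and r_max >= traj.box.min() / 2:
        raise ValueError(
            f"r_max {r_max} exceeds half the smallest box edge "
            f"({traj.box.min() / 2:.2f} A)"
        )
    shared = set(centers.tolist()) & set(probes.tolist())
    n_self = len(shared)

    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    if edges[-1] < r_max:
        edges = np.append(edges, edges[-1] + bin_width)
    counts = np.zeros(edges.size - 1, dtype=np.float64)
    expected_per_vol = 0.0  # sum over frames of centers * probe density
    densities = []
    chunk = max(1, int(2e6 // max(probes.size, 1)))
    for f in range(traj.n_frames):
        box = traj.box[f] if traj.box is not None else None
        coords = traj.coords[f]
        for start in range(0, centers.size, chunk):
            sub = centers[start:start + chunk]
            d = _min_image_dist(coords[sub], coords[probes], box)
            h, _ = np.histogram(d.ravel(), bins=edges)
            counts += h
        if n_self:
            counts[0] -= n_self  # remove the zero self distances
        if box is not None:
            vol = float(np.prod(box))
        else:
            # fall back on the bounding volume of the probe cloud
            span = coords[probes].max(0) - coords[probes].min(0)
            vol = float(np.prod(np.maximum(span, bin_width)))
        dens = probes.size / vol
        densities.append(dens)
        expected_per_vol += centers.size * dens

    shell_vol = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = shell_vol * expected_per_vol
    g = counts / norm
    centers_r = (edges[:-1] + edges[1:]) / 2
    return RDFProfile(centers_r, g, float(np.mean(densities)), bin_width,
                      r_max, counts)
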