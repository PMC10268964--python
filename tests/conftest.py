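import numpy as np
import pytest

from memtraj.core import Topology, Trajectory

TOY_PDB = """\
CRYST1   40.000   40.000   40.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.674   6.548  -4.129  1.00  0.00           C
ATOM      4  N   ALA A   2       9.902   5.600  -3.550  1.00  0.00           N
ATOM      5  CA  ALA A   2       8.928   5.835  -2.530  1.00  0.00           C
ATOM      6  C   ALA A   2       9.385   5.190  -1.204  1.00  0.00           C
ATOM      7  N   GLY A   3       9.100   3.900  -1.101  1.00  0.00           N
ATOM      8  CA  GLY A   3       9.471   3.105   0.050  1.00  0.00           C
ATOM      9  C   GLY A   3       8.350   2.297   0.714  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return str(path)


def ca_topology(n_res: int, chain: str = "A", first_resid: int = 1) -> Topology:
    """Minimal one-C-alpha-per-residue topology for hand-built trajectories."""
    return Topology(
        names=["CA"] * n_res,
        elements=["C"] * n_res,
        resids=list(range(first_resid, first_resid + n_res)),
        resnames=["ALA"] * n_res,
        chainids=[chain] * n_res,
    )


def static_trajectory(coords: np.ndarray, n_frames: int,
                      box=None) -> Trajectory:
    """Trajectory repeating one frame."""
    return Trajectory(np.tile(np.asarray(coords, float), (n_frames, 1, 1)),
                      box=box)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
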