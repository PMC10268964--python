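# memtraj

Comparative molecular-dynamics trajectory analysis for membrane receptor
complexes — built around the question of how ligand binding at an
extracellular domain is felt on the other side of the membrane. The target
use case is an inhibitory immune receptor (an NKG2A/CD94-type heterodimer
bound to an HLA-E-like ligand) where the proposed transduction chain runs
from ligand contact, through juxtamembrane linker reorganization and a
changed transmembrane helix crossing angle, to solvent exposure of the
intracellular ITIM tyrosines. Every analysis in that chain is implemented
here as a small, composable library plus a study driver that compares
labelled ensembles (e.g. bound complex vs apo receptor) replica by replica.

## What it computes

* **Dynamic cross-correlation matrices (DCCM).** For Cα atoms *i*, *j*,

  C<sub>ij</sub> = ⟨Δr<sub>i</sub>·Δr<sub>j</sub>⟩ /
  √(⟨Δr<sub>i</sub>²⟩⟨Δr<sub>j</sub>²⟩),

  with Δr the displacement from the time mean after superposing frames on
  an averaged reference. Domain-pair **correlation densities** aggregate
  the matrix: the signed sum of C<sub>ij</sub> over a domain pair divided
  by the product of the two domains' residue counts. **Differential
  matrices** subtract two models elementwise.
* **Essential dynamics.** Mass-weighted covariance PCA: eigenvalues
  (Å²·amu), cumulative variance, per-frame mode projections, and per-atom
  mode "arrow" fields for visualization.
* **Superposition and fluctuations.** Weighted Kabsch fits, per-frame RMSD
  series, per-residue RMSF about the time-averaged structure and
  B-factors B = (8π²/3)·RMSF².
* **Geometry.** Tilt angles of COM-difference vectors against a unit-cell
  axis, transmembrane helix crossing angles from end-to-end Cα vectors,
  COM distance series, and 2D angle-occupancy maps.
* **Interactions.** Geometric hydrogen bonds (donor–acceptor ≤ 3.0 Å and
  D–H···A ≥ 135° by default), occupancy percentages, distance-below-
  threshold frame fractions, and minimum-image contact-pair counts.
* **Solvation.** Radial distribution functions g(r) of water (or any probe
  selection) around tagged atoms, normalized with the instantaneous box
  volume.

A first-class **synthetic data generator** builds two-chain receptor
systems (IC/TM/EC domains, ligand body, implicit membrane slab with
144 lipid sites per leaflet at 65 Å²/lipid, ideal-gas solvent) whose
trajectories have *known* statistical and geometric ground truth:
designed inter-domain Pearson correlations, scheduled rigid-body domain
rotations, hydrogen-bond triplets with exact geometry. Every analysis
stage is validated against that ground truth.

## Worked example

Generate a bound-complex analog in which the extracellular domain of the
signalling chain and the ligand move with designed correlation ρ = 0.6,
then recover that correlation from the trajectory:

```python
import numpy as np
import memtraj as mt

spec = mt.receptor_spec(seed=1, frames=2000, sigma=0.4,
                        block_design=[("EC_A", "LIG", 0.6)], membrane=False)
topo, part, traj, manifest = mt.generate_study(spec)

per_dom = part.atom_indices(topo, names=["CA"])
anchor = np.sort(np.concatenate(
    [per_dom[d] for d in ("IC_A", "TM_A", "TM_B", "EC_B")]))
ca = np.sort(np.concatenate(list(per_dom.values())))

ccm = mt.dccm(traj, topo, selection=ca, align_selection=anchor)
dm = mt.domain_matrix(ccm, part, topo)
print(dm.to_frame().round(2))
```

prints

```
      IC_A  TM_A  EC_A  TM_B  EC_B   LIG
IC_A  0.02 -0.01 -0.00 -0.01  0.00  0.00
TM_A -0.01  0.04 -0.00 -0.01 -0.01 -0.00
EC_A -0.00 -0.00  0.72  0.00  0.00  0.61
TM_B -0.01 -0.01  0.00  0.04 -0.01  0.00
EC_B  0.00 -0.01  0.00 -0.01  0.01 -0.00
LIG   0.00 -0.00  0.61  0.00 -0.00  0.72
```

The EC_A×LIG density (0.61) recovers the designed ρ = 0.6; diagonal
blocks read (1 + (n−1)·ρ<sub>intra</sub>)/n ≈ 0.72 for n = 30 residues at
internal correlation 0.7; everything else is noise around zero. Note the
alignment anchor: superposition removes net rigid-body motion, so the
frames are aligned on domains *outside* the correlated pair (see
`docs/methods.md` for why that matters).

The same workflow is available from the shell:

```sh
memtraj generate --seed 3 --frames 200 --design EC_A:LIG:0.6 --out gen
memtraj run --config study.yaml     # models, frame window, stage toggles
memtraj report --dir out
```

`run` writes per-model CSVs (DCCM, domain matrix, RMSF/B-factor,
eigenvalues, angle and distance series, H-bond occupancy, contacts, RDF),
differential domain matrices for every model pair, and a `manifest.json`
recording every parameter in effect.

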