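# Methods

This note documents the models and numerical choices behind memtraj: what
each analysis computes, what the synthetic ensembles emulate (and what
they do not), and the design decisions taken where more than one
reasonable convention exists.

## Data model

A `Topology` holds atoms (name, element, mass from standard atomic
weights) grouped into residues and chains; residue numbering is kept
1-based as printed in PDB files and domain ranges are inclusive on both
ends. A `Trajectory` carries coordinates in Å (XTC's native nm are
converted on read), per-frame orthorhombic box edges, and optional
timestamps in ns. Triclinic cells are rejected explicitly rather than
silently mishandled. The default `FrameSelection` keeps the second half of
the frames at stride 1 — the convention of discarding the first half of a
production run as equilibration — and is fully overridable.

Stripping: analyses take explicit atom selections, so a "stripped" protein
view and a full view with solvent coexist on the same trajectory; the
solvent-dependent RDF stage and the protein-only stages simply use
different selections.

## Superposition, RMSD, RMSF

`kabsch_fit` solves the weighted least-squares superposition (proper
rotation; the reflection branch is excluded) via
`scipy.spatial.transform.Rotation.align_vectors`, with an explicit
degeneracy check: fewer than 3 atoms or a rank-deficient cross-covariance
(collinear points) is an error, not a warning. RMSD series fit each frame
on the analysis selection and report on the same selection.

RMSF uses a two-pass reference: frames are aligned to frame 0, averaged,
and then re-aligned to that average before fluctuations are accumulated.
The alignment selection and the reporting selection are independent (one
can align on the receptor only and still report ligand residues).
B = (8π²/3)·RMSF² is applied elementwise and exactly.

Fitting removes six rigid-body degrees of freedom, which biases fitted
fluctuations low by roughly 2/(3N) in variance for N independently moving
units, and a finite alignment set leaves residual noise of the same
order. The validation ensembles are sized so these O(1/N) terms sit well
inside the stated tolerances (see "Validation sizes" below).

## Cross-correlation and domain densities

The DCCM is the normalized covariance of Cα displacement vectors about
their time mean, computed after superposing frames on the time-averaged
structure. Zero-variance atoms raise an error naming the residue. Domain
aggregation is the signed block mean: sum of CC_ij over the pair divided
by |P|·|Q|, with self terms included on the diagonal (that is the only
normalization consistent with dividing by the product of the residue
counts). Replica averaging is an elementwise mean of per-replica matrices
and is applied before domain aggregation; by linearity the order does not
matter, which the tests verify. Differential matrices are elementwise
differences of same-shaped matrices (range [−2, 2]).

**Alignment caveat (important).** A displacement field in which all pairs
of a block are positively correlated necessarily carries net rigid-body
motion: summing ⟨Δr_i·Δr_j⟩ over all pairs gives ⟨|Σ_i Δr_i|²⟩ ≥ 0, and
after superposition that common mode is exactly what has been removed, so
a field whose rigid modes were subtracted cannot have an all-positive
correlation block. Consequently, self-aligned DCCM of a globally
correlated set *must* understate the correlation (for a uniformly
ρ-correlated set of n atoms the self-aligned estimate collapses to about
(ρ − (1+(n−1)ρ)/n)/(1 − (1+(n−1)ρ)/n), near zero). `dccm` therefore
accepts an `align_selection` independent of the analysis selection; in
comparative studies the anchor should be a part of the system whose motion
is independent of the domains of interest (here: the domains not named in
the correlation design). A finite anchor of m atoms leaves a residual of
order 1/m — with ~60 anchor atoms the recovered block correlation runs
about +0.02 above the design, within the ±0.05 recovery tolerance.

## Essential dynamics

PCA diagonalizes the covariance of mass-weighted coordinates √m_i·x_i
after superposing frames on the *first* frame — deliberately a different
reference than the correlation stage's averaged structure, matching the
two protocols' conventions. Eigenvalues (Å²·amu) are sorted descending,
tiny negative values are floored at zero, and eigenvector signs follow a
fixed convention (largest-magnitude component positive) so results are
reproducible run to run. Projections are dot products of mass-weighted
displacements with an eigenvector; their variance equals the eigenvalue
by construction. Mode arrows back-transform an eigenvector to real space
by dividing each atom's components by √m. The lipid-phosphorus variant is
the same operation under a P-atom selection; there is no separate code
path. No truncation to "the essential subspace" is imposed; the full
spectrum is reported.

## Geometry

Angles are reported in degrees on [0, 180] without folding to [0, 90],
preserving the distinction between crossed and splayed helix arrangements
and tilts past 90°. Tilt angles take a COM-difference vector (mass
weighted by default; single-atom selections bypass weighting) against a
unit-cell axis, z being the bilayer normal. The helix axis for crossing
angles is the literal end-to-end Cα vector of the stated residue range;
an SVD-fitted axis is available as an option but is not the default.
Residue ranges are treated as unordered endpoints and normalized. No
minimum-image correction is applied inside COM/vector math — the molecule
is assumed whole; a wrapping pre-pass exists separately for periodic
neighbour searches.

## Hydrogen bonds and contacts

A hydrogen bond in a frame requires donor–acceptor distance ≤ 3.0 Å *and*
D–H···A angle at the hydrogen ≥ 135° (both defaults overridable); the
angle cutoff is a lower bound because larger angles are more linear.
Donor hydrogens are found by element within the donor's residue,
confirmed covalent by a < 1.2 Å distance; a donor without a hydrogen is
an error naming the atom. Occupancy is the percentage of analyzed frames
in which a triplet satisfies both criteria; tightening either cutoff can
only lower it. Distance-below-threshold fractions support both the
minimum atom-pair distance (default, the terminal-atom reading) and COM
distance.

Contact counting uses a cKDTree per frame with the minimum-image
convention whenever a box is present (cutoff must stay below half the
smallest edge) and equals a brute-force double loop exactly, which the
tests assert. The contact cutoff is not standardized in the literature;
the default is the common 4.5 Å heavy-atom convention, it is exposed in
the configuration, and it is stamped into every contacts output header.
Membrane contacts are ordinary contacts against the lipid-site selection.

## Solvent RDF

g(r) bins center–probe minimum-image distances and divides each bin by
the ideal-gas expectation: exact shell volume (4π/3)(r₂³−r₁³) — not the
4πr²Δr approximation — times the probe number density times the number of
center–frame observations. The density uses the probe count and the
instantaneous box volume of each frame, so constant-pressure boxes are
normalized correctly. Self pairs are excluded when the selections
overlap. Defaults: 0.1 Å bins to r_max = 10 Å; r_max must stay below half
the smallest box edge. Multiple centers are averaged.

## The synthetic generator

The generator builds what the analyses need to be falsifiable, not a
physical simulation:

* **Layout.** Two chains with intracellular, transmembrane and
  extracellular domains plus a ligand chain; domains are ideal poly-Ala
  helices (N, CA, C, O, CB per residue; 1.5 Å rise, 2.3 Å radius,
  100°/residue) with TM helices vertical through the slab.
* **Membrane.** Two leaflet grids of phosphorus pseudo-sites; the leaflet
  cross-section is exactly sites × area-per-lipid (defaults 144 sites at
  65 Å², i.e. 9360 Å², and the box cross-section matches it). Lipids do
  not move.
* **Displacements.** Per-atom Gaussian fluctuations with per-axis σ
  (default 0.5 Å), independent outside the correlation design. Domains
  named in the design share an atom-level correlation matrix: intra-domain
  0.7, designed pairs at their target ρ. If that matrix is not positive
  semidefinite it is projected to the nearest correlation matrix
  (statsmodels `corr_nearest`) and the *achieved* values are written to
  the ground-truth manifest — the repair is never silent, and recovery
  tests compare against what was actually simulated.
* **Rigid programs.** Scheduled rotations (step or linear ramp) about
  membrane-frame axes through the domain's center of mass, giving exact
  angle references.
* **Fixtures.** Donor–H–acceptor triplets placed with exact requested
  distance and angle each frame, optionally toggled on a frame schedule
  for occupancy oracles.
* **Solvent.** An ideal gas redrawn uniformly each frame (outside the
  slab when a membrane is present), so the RDF reference is exactly 1; an
  optional exclusion sphere around tag points yields a step-shaped RDF.

What this does *not* emulate: force-field energetics, water structure,
lipid dynamics, anharmonic or state-switching protein motions, and
autocorrelated frames (every frame is independent). Passing tests
therefore demonstrate that the estimators recover known statistical and
geometric structure at the stated sample sizes — not that any biological
conclusion from real trajectories is reproduced. Real multi-microsecond
ensembles with their absolute RMSD magnitudes, hydrogen-bond percentages
and RDF differences are outside desk-scale reach, and no such numbers are
asserted anywhere in the package.

## Validation sizes

The test suite and `scripts/acceptance.py` use problem sizes chosen so
that statistical tolerances sit several standard errors from failure:
correlation recovery on 20 designed residues among 80 total at 10,000
frames (±0.05 band, sampling error ≈0.01, anchor residual ≈+0.02);
differential discrimination over 20 seeds at 1,000 frames per model; RMSF
closed form at 5,000 frames with residue values averaged over five
independent atoms (per-residue noise ≈0.26%, alignment bias ≈0.13%,
tolerance 2%); RDF bulk check with 20,000 probe placements sampled
probe-against-probe (per-bin Poisson noise ≈0.3% against a 2% band). The
whole suite runs in about a minute on one CPU; the acceptance script in a
few minutes.

## Known limitations

* Only orthorhombic cells; no velocities; no bond topology beyond the
  donor-hydrogen convention.
* The end-to-end Cα helix axis is noisy for short or frayed helices; use
  the fitted-axis option there.
* Self-aligned DCCM of a globally correlated selection understates the
  correlation by construction (see above); choose the alignment anchor
  deliberately.
* `occupancy` for a pair that never bonds requires the donor/acceptor
  context to distinguish "0%" from "unknown pair".
* The PDB writer emits minimal records (no CONECT, no altLocs) and wraps
  residue numbers above 9999.
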