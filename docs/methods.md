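# Methods

This note documents the models, conventions and numerical choices behind
gpcrswitch, and what its synthetic validation does and does not establish.

## Units and conventions

Coordinates and distances in Å, times in ps, energies in kcal/mol, angles in
degrees. Atom indices are 0-based internally; residue numbers are always the
author/PDB numbering. Water is any residue named HOH/WAT/TIP3/SOL
(configurable) and is represented by its oxygen atom.

## Generic numbering

Ballesteros–Weinstein indices `H.PP` are supplied as explicit TSV tables
(columns `bw_index, resseq, resname`). Within a helix, residue numbers must
be strictly increasing and consecutive with the generic positions
(`resseq(p2) − resseq(p1) = p2 − p1`); this invariant is validated on load
and lets a single anchor per helix resolve any position on it
(`BWTable.from_anchor`). The package does not compute generic numbers by
alignment — for real structures the table should come from a curated source
such as GPCRdb, and the loader cross-checks residue names against the PDB.

## Atom-role selection

Named roles keep the metric definitions residue-type-safe: `CA`, `ring_C4`
(the para ring carbon of Phe/Tyr, PDB name CZ — counting the ring from the
attachment carbon C1 = Cγ, the fourth carbon is Cζ), `arg_CE`, `glu_CD`,
`tyr_OH`, `carboxylate_O_pair` (OD1/OD2 or OE1/OE2), `guanidinium_N_set`
(NE/NH1/NH2). A role applied to an incompatible residue type (e.g. a ring
carbon on a leucine mutant) is a hard error, not a silent fallback.
Arginine has no "Cε" in PDB nomenclature (side chain CB–CG–CD–NE–CZ);
`arg_CE` selects CZ, the guanidinium carbon, which is the standard carbon
probe for ionic-lock distances and the symmetric partner of Glu Cδ.

## Switch classification and engagement

Each switch is a per-frame Euclidean distance (plain, no minimum image —
intramolecular separations never span the box in wrapped trajectories; a
minimum-image option exists in principle through pre-wrapped input) compared
against a threshold with an inclusive boundary: engaged ⟺ d ≤ threshold.
Defaults: 9.5 Å for the F6.44/F6.41 activation switches, 5 Å for the
R3.50–E6.30 ionic lock. The D3.49–R3.50 salt bridge has no published
criterion; the package uses the standard min-over-pairs carboxylate-O ×
guanidinium-N distance with a 4.0 Å threshold, exposed in the configuration.
The Y7.53 orientation has no published threshold either and is therefore
reported as two raw distances (to Cα 3.50 and Cα 2.40), never binarized.

Pooled engagement over replicates is frame-weighted
(`100 · Σ engaged / Σ frames`), matching a percentage computed over total
simulation time rather than a mean of per-replicate means. No equilibration
discard and no stride are applied by default; both are configurable.

## Helix axis and rotation

The axis of a Cα span (≥ 4 residues) is fitted in three stages: (i) the SVD
null direction of the second differences `P[i+1] − 2P[i] + P[i−1]`, which
for a constant-rise helix lie exactly in the plane normal to the axis — this
is exact on ideal helices for any residue count, whereas the largest-variance
principal direction of the raw points is biased by up to ~2° whenever the
span covers a non-integer number of turns; (ii) a cylinder fit minimizing
the spread of radial distances; (iii) a full parametric helix fit (axis,
in-plane center, radius, rise, twist, phase) in all three coordinates, the
maximum-likelihood refinement under iid coordinate noise. Stages (ii) and
(iii) leave an exact initial axis untouched. With σ = 0.3 Å noise on a
24-residue helix the fitted axis stays within 2° of truth in 1000 of 1000
Monte-Carlo draws; a 17-residue span is at the information limit for that
bound (worst draw ~2.2° even for the ML estimator).

Rotation of a frame relative to the reference is the circular mean over span
residues of each Cα's angular-coordinate change about the *reference* axis;
the sign is right-handed about the axis, the reference scores exactly 0, and
residues with projection radius < 0.5 Å are excluded (angle undefined near
the axis). Before measurement each frame is superposed onto the reference on
the receptor-core Cα set (everything except the measured span), so a global
rigid-body motion of the frame leaves the measured rotation unchanged — the
reference is the crystal structure by default, and the alignment protocol is
a package decision since none is published. Series are unwrapped assuming
|Δangle| < 90° between consecutive frames. Both study spans (6.44–6.50 and
6.44–6.60) ship as named presets; neither is privileged.

## Solvation and contacts

Water occupancy is a per-voxel count of water-oxygen observations (default
1.0 Å voxels). `bulk_relative` normalization divides the per-frame voxel
occupancy by 0.0334 Å⁻³ × voxel volume — the number density of pure water
at 300 K — so 1.0 means bulk-like hydration. Raw counts conserve the total
number of in-bounds observations exactly. Grids export to OpenDX text for
VMD/PyMOL.

Ligand contacts use heavy atoms only (robust to hydrogen placement): a
residue is in contact in a frame when any of its heavy atoms is within the
cutoff (default 3 Å) of any ligand heavy atom; the table reports the
fraction of frames per residue, descending, top-10 by default. Ligand RMSD
is computed after least-squares superposition of the receptor Cα set onto
the reference — the ligand is *not* re-fitted, so the value reports genuine
ligand motion in the receptor frame. The near-residue water count is the
per-frame mean number of water oxygens within the cutoff (default 2 Å) of
the selected atom, counting oxygen positions.

## Well-tempered metadynamics reconstruction

Hills logs are whitespace text (time, cv1, cv2, σ1, σ2, height, bias
factor), one file per walker, `#`-prefixed headers ignored; walker files are
merged and time-sorted with ties broken by walker id. Logged heights are
assumed to be the **already-tempered** deposited values (the convention of
the common metadynamics plugins), so reconstruction applies only the
γ/(γ−1) prefactor and never re-applies the tempering decay; a flag covers
logs storing nominal heights. The estimate `F = −(γ/(γ−1)) Σ Gaussians` is
evaluated exactly (chunked, to bound memory) on a regular grid — default
120×120 over [6, 14] Å², which covers the crystal point and both activation
states with the 0.1 Å hill width well resolved — and referenced to min 0.
No reweighting is applied; the plain well-tempered estimate is presented.
State labeling partitions the CV plane at 9.5 Å per CV (threshold inclusive
on the active side) into inactive, intermediate, active, and the
mechanistically disallowed quadrant reported as `forbidden_path`.

## Synthetic data: what it emulates, what it does not

* **Switching dynamics**: the engaged flag follows a stationary two-state
  Markov chain with engaged fraction *p* and relaxation scale `dwell`
  frames (transition probabilities `(1−p)/dwell` out of and `p/dwell` into
  the engaged state, autocorrelation `(1 − 1/dwell)^k`); the distance is
  the state's mean plus iid Gaussian noise. Defaults straddle the
  thresholds by ≥ 3σ (8.5/10.5 Å, σ 0.25 for the 9.5 Å switches; 3.5/7.0 Å,
  σ 0.4 for the 5 Å lock), so classification is effectively exact and
  recovery errors measure only chain sampling noise. The CI used in
  validation inflates the binomial variance by the integrated
  autocorrelation factor `2·dwell − 1`.
* **Helices**: ideal geometry (rise 1.5 Å, twist 100°, radius 2.3 Å),
  rigid imposed rotations, optional global tumbling nuisance.
* **Solvation**: iid uniform water placements per frame at fixed count
  `round(density·V)`; the pinned-water option places a prescribed mean
  number of waters inside the marker sphere and excludes all others from
  it, so the near-marker count recovers the pinned mean exactly up to
  Bernoulli noise.
* **Langevin walker**: overdamped (Brownian) dynamics on an analytic 2D
  potential — inertia adds nothing at this scale — with on-the-fly
  well-tempered deposition (`w = h₀ exp(−V/k_B ΔT)`), six walkers sharing
  the bias with a 20 ps exchange interval (each walker always sees its own
  pending hills), reflecting bounds, and the published hill parameters as
  defaults (0.1 kcal/mol, σ 0.1 Å, one hill per 4 ps, γ = 10, 300 K). The
  bias and its analytic gradient are accumulated on a 0.05 Å grid and
  bilinearly interpolated; diffusion 0.05 Å²/ps and timestep 0.05 ps keep
  the stiffest mode stable. Ground-truth labels are always drawn before
  coordinates are built, never inferred from them.

Passing recovery tests on these generators establishes that the measurement
layer is correct and unbiased, not that real receptor trajectories would
reproduce any published percentage: the generators have no membrane, no
force field, no cross-correlation between switches, and literal two-state
distance dynamics. Real-data caveats (PBC wrapping, missing residues,
alternate conformations) are handled only to the extent the loaders
validate their inputs.

## Problem sizes in the validation

Engagement recovery uses 5 replicates × 20 000 frames per switch (dwell 50,
giving ~2000 effective samples per switch and ~1.5-point CI half-widths);
rotation recovery 240-frame sinusoids; the Langevin validation 6 × 100 000
steps (5 ns per walker, 7500 hills), after which basin locations are
recovered within one 0.2 Å analysis cell and the 1.5 kcal/mol barrier
within ~10–16% across seeds — comfortably inside the 20% band expected for
a plain well-tempered estimate with 0.1 kcal/mol hills. The analysis grid
for basin location uses 0.2 Å cells because the residual hill-scale
ruggedness of the reconstructed surface (~0.1 kcal/mol) exceeds the
curvature of the wells over a finer cell.

## Known limitations

* No kinetic or hidden-Markov modeling of switch dynamics; states are
  threshold classifications only.
* No helix kink/bend/tilt metrics; only axial rotation.
* No water-channel pathfinding; the occupancy grid is the product.
* No on-the-fly biasing of real MD; the only dynamics engine is the toy
  Langevin walker.
* Packaged BW tables for the two study structures are not included: the
  publication pins only a handful of anchors, so full tables must be
  supplied by the user (one anchor per helix suffices via the consecutive
  rule).
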