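# Methods

This note documents the models and numerical choices behind `rehydra`:
what each analysis computes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Data model and conventions

Coordinates are Å (PDB native), times ps, residue indexing 0-based
internally (display layers may renumber).  Trajectories are ordered
frames over one topology; a replica set is N trajectories of the same
system under one condition (`solution`, `vacuum@field`,
`rehydration@field`, field in V/nm).  The on-disk reference format is
multi-model PDB; parsing and writing go through biotite, with a
pre-scan that turns malformed records into line-numbered errors and
atom-count mismatches into errors naming the offending MODEL.  GROMACS
nm-based formats are supported only through external conversion at the
adapter boundary; all internal numbers stay Å.  Water is recognised by
residue name (HOH/SOL/WAT/TIP4, extendable per call).  Elements come
from PDB columns 77–78 when present, otherwise from an atom-name
heuristic that errors rather than silently guessing carbon.

Trailing analysis windows take either the last fraction of frames or
the last duration.  A fraction-f window keeps round(f·n) frames (so its
length is within one frame of f·n for any grid); a duration window
keeps frames with time > t_end − duration and refuses, rather than
clamps, a window longer than the trajectory.  The study convention —
the final 50 ns of 200 ns trajectories — is `last_fraction=0.25`, the
package default.

## Superposition, RMSD and RMSF

Superposition is Kabsch's closed-form least-squares fit via SVD, with
the determinant correction that excludes reflections: a chiral
structure fitted to its mirror image retains a non-zero residual.
Weights are uniform over the selection by default (a `weights` argument
exists); for Cα-only selections this differs negligibly from
mass-weighting.  Degenerate inputs (fewer than three points, or
collinear sets, detected by rank of the centered coordinates at 1e-10
tolerance) are errors.

RMSD series evaluate the fitted residual per frame against one of three
references: the trajectory's own first frame (RMSD_f), a single shared
external frame such as the solution control's final structure (RMSD_s),
or a per-replica "parent" frame, paired by replica index, such as the
final frames of the zero-field rehydration replicas (RMSD_zf).  The
shared-reference variant is the default reading for RMSD_s, with the
per-replica mapping available; the index rule for parent pairing
(replica i ↔ parent i) is an explicit, documented assumption.  Replica
averages are pointwise means with pointwise sd; time grids must match
within 1e-6 ps.

RMSF concatenates all replicas of a condition, superposes every frame's
selection onto the first frame, computes the coordinate-wise average
structure, re-superposes each frame onto that average (one refinement
pass, no iteration to convergence), and takes per-atom
RMSF_i = √⟨|x_i − x̄_i|²⟩ mapped to residues (Cα per residue by default;
a mean over residue atoms for wider selections).  Two properties of
this estimator are worth knowing:

* With isotropic per-atom jitter of amplitude σ_i, the expected RMSF is
  σ_i√3 only up to rigid-body-fit effects.  The uniform-weight fit
  absorbs six degrees of freedom and, when amplitudes are
  heterogeneous, preferentially aligns the large-σ atoms, inflating the
  apparent fluctuation of quiet residues by order ⟨σ²⟩/(N σ_i²) in
  variance.  For a globular system of ~130 residues with amplitudes
  (0.2, 0.4, 0.8) Å the per-class bias stays below ~4 %; for small or
  strongly elongated systems it can reach tens of percent.  Tests
  therefore assert parameter recovery (class means within 5 %) at
  protein-like size, and exact zeros for static inputs.
* Because the provisional fit reference is the first frame of the
  concatenation, replica-order permutation changes the result only at
  the accuracy of the single refinement pass (observed ~1e-5 Å on test
  systems), not to machine precision.

## Collision cross section (projection approximation)

The molecule is the union of van-der-Waals spheres (Bondi-style radii
shipped with the package; the same table serves SASA and volume — the
projection approximation carries no charge or temperature dependence).
For each of `n_rotations` (default 300) uniformly random orientations,
the shadow area of the projected disc union is integrated by scanlines:
each line contributes the exact union length of its chord intervals,
and lines are spaced `grid_resolution` (default 0.2 Å) apart with the
grid origin jittered uniformly per orientation.  The jitter makes the
orientation average unbiased (discretisation error becomes zero-mean
noise instead of a systematic offset); a single-sphere CCS evaluates to
πr² within ~0.03 % at defaults.  The reported uncertainty is the
Monte-Carlo standard error over orientations; a fixed seed fixes the
value exactly.

Projection-approximation CCS values systematically undershoot measured
ion-mobility cross sections; `apply_ccs_calibration` multiplies by an
empirical factor (default 1.14).  Report tables round calibrated values
to integer Å².  Power-law calibrations against higher-grade scattering
models are out of scope.

`convexity_ratio` returns A_s(probe 0)/Ω on identical radii.  Cauchy's
surface formula makes this exactly 4 for convex bodies; since the
convex hull's shadow contains the body's shadow while its surface is no
larger, the ratio is ≥ 4 in general, so the excess over 4 is a
concavity diagnostic.

## Solvent-accessible surface area and envelope volume

SASA is Shrake–Rupley: each atom's accessible sphere (r_i + probe,
probe default 1.4 Å) is sampled on a deterministic golden-section
spiral (default 960 points, fewer than 16 rejected); a point is exposed
if outside every neighbour's accessible sphere (neighbours found by a
k-d tree).  The two-sphere configuration reproduces the spherical-cap
closed form to <1 %.  Per-atom areas are exposed for residue-level
aggregation.

Envelope volume counts voxels (default 0.3 Å) whose centers fall inside
the sphere union, on a grid padded by the largest radius.  The voxel
size must not exceed the smallest atomic radius (else spheres could be
missed entirely).  Error decreases with voxel size (single spheres are
recovered within 2 % at 0.2 Å); the method is the plain van-der-Waals
envelope, with no probe inflation — it reproduces the expected
similarity scaling (s³ under uniform scaling of coordinates and radii)
and the qualitative swelling upon rehydration.

Windowed ensemble statistics pool every windowed frame of every replica
into one sample and quote its mean and sd (ddof = 1).  Vacuum-condition
structures are single conformations per replica and enter without a
window.

## Compaction deltas

For each metric the rehydrated mean R_f at field f is compared with the
vacuum mean V_f at the same field and with the single solution mean S:

    Δ_vs_vacuum   = round( mean_f 100·(R_f − V_f)/V_f )
    Δ_vs_solution = round( mean_f 100·(R_f − S)/S )

with rounding half away from zero.  Per-field percent changes are
averaged *after* division (not a ratio of averages), which is the
convention that reproduces the reference report rows used in the test
suite.  Full-precision values live in the JSON outputs; rounding is a
table-layer concern only.

## Contacts and hydrogen bonds

A contact between two protein residues exists in a frame when any
atom–atom pair (hydrogens included — nothing in the definition excludes
them) is within 3.5 Å, boundary inclusive; comparisons use squared
distances so the boundary is exact to floating point.  Sequence
neighbours are not excluded, so near-diagonal bands are expected.  The
default engine is a cell-list grid at cutoff resolution (linear-time in
atoms); a brute-force all-pairs path is retained and tested to agree
exactly.  Occupancy is the mean of the binary contact matrix over all
windowed frames pooled across replicas; difference maps subtract one
condition's occupancy from another's (antisymmetric under swap, ±1 at
the endpoints); composite maps pack two difference maps into strictly
lower/upper triangles with a zero diagonal.  Single-frame "trajectories"
(e.g. vacuum structures) are valid inputs throughout.  No periodic
minimum-image handling is applied: inputs are whole, centered
molecules.

Hydrogen bonds use a geometric criterion in the gmx-hbond style: donor
= N/O with an H within 1.2 Å (attachment by distance, no bond table),
acceptor = N/O, bond when D–A ≤ 3.5 Å and H–D–A angle ≤ 30°, both
configurable.  Only protein↔solvent pairs are counted, each distinct
donor–acceptor pair once.  A frame without solvent counts zero with a
warning rather than erroring.

## Synthetic generator

The generator replaces molecular dynamics with a process whose every
statistic has a closed form:

* **Toy protein.**  The Cα trace is a helical arc wound on a sphere and
  walked in exact 3.8 Å chord steps (the trans-peptide Cα–Cα distance);
  the sphere radius follows from the surface area needed for N residues,
  giving non-adjacent residue separations ≥ ~4.7 Å and a globular mass
  distribution.  The winding, rather than a straight helix, is
  deliberate: a straight N-residue helix is a rod whose end residues
  carry most of the rigid-body-fit leverage, which distorts
  superposition-based statistics in a way no globular protein shows.
  Each residue carries CA and, as the per-residue atom budget allows,
  an amide-like N with outward-pointing H (hydrogen-bond donors), a
  carbonyl-like O (acceptors), and seeded dummy side-chain carbons.
  Backbone placement is seed-independent; side chains are not.
* **Rehydration process.**  x(t) = x̄ + (X − x̄)[s + (1 − s)(1 − e^(−t/τ))] + ε:
  compacted by scale s (default 0.8) about the centroid at t = 0,
  exponential relaxation (τ default 10 ps) to the expanded reference X,
  plus independent isotropic Gaussian jitter with per-residue amplitude
  σ_i (default 0.3 Å) each frame.  Defaults mirror the emulated study
  design: five replicas, 200 frames at 1 ps.  Per-replica seeds are
  master seed + 1000·replica, recorded in the ground-truth sidecar.
  Ground truth: final RMSD_f (Kabsch residual between compacted and
  expanded Cα sets), RMSF_i = σ_i√3, and compact/expanded shape ratios
  s² (areas) and s³ (volume) — the latter hold exactly only when radii
  scale with coordinates; for fold compaction at fixed atomic radii they
  are approached from above.
  Noise is uncorrelated between atoms and frames by design (closed-form
  ground truth beats realism here); real thermal motion is correlated
  along the chain and in time, so passing recovery tests demonstrates
  estimator correctness, not robustness to correlated noise.
* **Solvent.**  Waters are rigid 3-site (O–H 0.96 Å, 104.5° angle), no
  virtual site — geometric counting needs none.  Planted waters sit
  with O exactly 2.9 Å from a chosen N–H donor along the N→H direction
  (angle ≈ 0), with donor sites chosen so every planted water is
  isolated (≥4.5 Å from all other protein N/O and other waters), making
  the planted count exact; spectator waters are placed beyond 8 Å.
  Requesting more bonded waters than isolated donor sites is an error.
* **Idealised fixtures.**  Single spheres and two-sphere dumbbells with
  explicit radii serve the analytic shape oracles (disc area, cap area,
  lens volume, far-separation additivity).

## Pipeline and reproducibility

The pipeline is configuration-driven (YAML): replica file lists per
condition, window, cutoffs, CCS/SASA/volume settings, seed, output
directory.  Validation resolves defaults and reports *all* problems at
once.  Stages: RMSD (all three schemes derivable from the configured
conditions), RMSF per condition, shape statistics with the compaction
table, contact/difference/composite maps, hydrogen-bond means.  Every
output embeds a configuration hash (output directory excluded, so
reruns elsewhere compare equal); numeric tables are written at fixed
precision and reruns with the same config and seed are byte-identical.
Per-frame CCS inside the pipeline reuses the configured seed per
evaluation, so shape series are deterministic regardless of evaluation
order.

Desk-scale defaults in the examples and tests (12–129 residues, 5
replicas, tens to hundreds of frames, 40–300 CCS orientations) were
chosen so the full battery runs in seconds to a few minutes on one
core; the statistics scale to production ensembles unchanged.

## Known limitations

* The projection approximation ignores scattering physics; only the
  multiplicative calibration is provided.
* Envelope volume is the probe-free van-der-Waals envelope; it is not
  a solvent-excluded (Connolly) volume.
* RMSF inherits the uniform-weight superposition biases described
  above; strongly heteroscedastic, small systems need care.
* No secondary-structure assignment, PBC unwrapping, or binary
  trajectory formats (XTC/DCD) — converters must produce multi-model
  PDB at the boundary.
* Hydrogen-bond detection is purely geometric; it knows nothing of
  energetics or of exotic donors.
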