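# Methods

`globulegeom` implements the quantitative analyses that surround a
cryo-electron-tomography study of TREX-coated mRNP globules: pairwise pose
statistics of a C2-symmetric complex on particle surfaces, iso-surface
particle morphometry, a multivalent-avidity occupancy model, constrained
Hill binding fits, and crosslink distance validation.  The real inputs to
such analyses (subtomogram-averaging pose tables, denoised tomograms,
filter-binding curves, crosslink lists) are replaced by a seeded synthetic
generator with recorded ground truth, so every stage is testable without
any experimental data.

## Pose model and conventions

A **pose** is a rigid placement of a reference complex: `x_tomo =
R @ x_model + c`, with `c` in Å.  Euler angles are **intrinsic,
right-handed X→Y→Z** in degrees (`R = Rx(α)·Ry(β)·Rz(γ)`), reported with
rotX, rotZ ∈ (−180°, 180°] and rotY ∈ [−90°, 90°].  At gimbal lock
(|rotY| = 90°) rotX carries the whole in-plane angle and rotZ is reported
as 0.  STAR pose tables carry a `_poseEulerConvention` item naming this
convention; tables in other conventions must be converted explicitly
(`formats.convert_euler_convention`).

## C2 symmetry resolution

The reference complex is two-fold symmetric, so composing either pose with
the symmetry operator C2 moves no atom and the relative rotation
`R = R_A⁻¹R_B` of a pair has four equivalent representatives
`C2^α·R·C2^β`.  The canonical representative is chosen by the marker rule:
the two symmetry-mate markers (the role played by the two THOC1 copies;
THOC5-K516 plays the center-marker role) are placed with both poses, all
four inter-marker distances are measured, and the assignment with the
globally closest matched pair wins; exact ties resolve to α = β = 0.  Two
consequences hold exactly and are property-tested: replacing either pose
by its C2-composed equivalent leaves the canonical rotation unchanged, and
canonical(B, A) is the transpose of canonical(A, B).  Considering only the
two representatives {R, R·C2} would break both properties, which is why
the four-assignment form is used.

Per-pair descriptors: center-marker distance, exhaustive closest-atom
distance, canonical Euler angles, spherical angles (physics convention: θ
polar from +Z, φ azimuth from +X, both of the A→B center vector in A's
model frame; coincident centers report θ = φ = 0 with a warning), and a
contact flag (closest-atom distance ≤ 10 Å by default).  Duplicate poses
(same particle, centers within 100 Å) are collapsed keeping the first by
input order before pair enumeration; cross-particle pairs are excluded.

The canonical rotation-angle distribution under uniform orientations (the
"null" against which orientation preferences are judged) has no simple
closed form: the marker rule's choice is correlated with the rotation
angle (empirically, plain-Haar angles are rejected at p < 1e-7).  The null
law is therefore defined by Monte-Carlo: an independently seeded scene
canonicalized by brute-force enumeration provides the reference sample for
a two-sample Kolmogorov–Smirnov test at α = 0.01.

## Synthetic scenes

Globules are ellipsoids.  Diameters (longest axis) are drawn from a
two-piece uniform on (min, median) ∪ (median, max) — median 450 Å, range
300–700 Å by default — so the configured median is the distributional
median.  Axis ratios default to [0.5, 1.0], matching the observed
sphericity spread; particle orientations are uniform.  Particles sit on a
jittered cubic grid with spacing above the largest possible extent, so
they never touch.  Complex centers sit `surface_offset` (default 50 Å)
outside the surface along the local normal — for a convex body this makes
the exact nearest-surface distance equal the offset.

The number of complexes per globule is a free parameter (the per-mRNP
copy-number distribution is not an experimental claim); the default
P(0..3) = (0.10, 0.40, 0.35, 0.15) makes multiple copies common and three
the maximum, matching the qualitative description of decorated particles.

Orientation modes:

* `uniform` — Haar-uniform via quaternion sampling (the null model);
* `fixed` — identity (degenerate control);
* `clustered` — the positive control: complexes dock the surface with a
  preferred face (model +Z along the outward normal, tangent frame built
  deterministically from the particle axes) and a fixed twist, perturbed
  by a rotation of half-normal magnitude with scale 1/√κ radians about a
  uniform axis.  Pose-level clustering about a global reference would
  cancel in pair-relative rotations; surface-docked clustering is both the
  physically meaningful alternative hypothesis and one that produces
  genuine pair-level orientation clusters.

Placement modes: `surface-random` (default) and `fixed-sites`, which
alternates two perpendicular surface sites so that within-particle pair
geometry is constant — used for embedding positive controls, where
cluster separation must dominate every standardized feature.  (Antipodal
sites were rejected: under C2 they create structural ties between marker
assignments that randomly conjugate the canonical rotation.)

Every scene records ground truth: pose-to-particle assignment and the full
descriptor set of every within-particle pair, enabling exact closure tests
(extraction on a scene returns exactly the recorded pairs).

All randomness flows from one `numpy.random.Generator` seeded by the
config; identical config + seed gives byte-identical outputs.

## Density rendering and blob morphometry

Particles render as ellipsoidal blobs with interior amplitude 1.0 and a
raised-cosine edge of full width 2 voxels in signed radial distance.  The
edge is positioned so the profile crosses the **measurement threshold
0.025** exactly at the nominal surface (edge center shifted inward by
0.799 half-widths): thresholding at 0.025 then recovers the true particle
boundary, and rendered-sphere volumes agree with (4/3)πr³ to ≪ 1% at
10 Å voxels.  A symmetric edge would bias volumes by > 10% at that
threshold.  No imaging physics is modelled (no CTF, missing wedge, or
noise texture); the threshold 0.025 is specific to this renderer's (and
the emulated tool's) intensity scale and is a required user parameter for
foreign maps.

`measure_blobs` labels voxels above threshold with 26-connectivity,
discards components under `min_voxels` (default 50), and reports per blob:
volume = voxel count × voxel³, centroid, and principal-axis extents —
the span of voxel projections onto the covariance eigenvectors, i.e.
max−min of voxel centers **plus one voxel size** (the enclosing voxel-box
extent).  The one-voxel addition matches the "dimensions enclosing the
volume" semantics of the emulated measurement tool, removes the
half-voxel-per-side underestimate of center-only spans, and gives a
one-voxel blob extent `voxel_size` instead of zero.  Sphericity is
shortest/longest extent (roundness is the 2-D analogue).  Components
touching the grid boundary are flagged and excluded from diameter
summaries by default.  Group comparisons use Welch's unequal-variance
t-test, two-sided; the degenerate zero-variance/equal-means case returns
p = 1 by convention.

## Occupancy (avidity) model

All concentrations come from `c = n / (N_A · (4/3)π(d/2)³)`.  Defaults
describe the median human mRNP: 8 introns × 2 UBMs per ALYREF = 16 UBM
sites in a 450 Å sphere → 557 μM (printed "560 μM" at 2 s.f.).  Occupancy
is single-site `L/(L + K_D)` (Hill h = 1; h is exposed for sensitivity
analysis): at K_D = 2.9 μM this gives 99.5% saturation.  The compaction
factor is contour length / globule diameter with 6 Å/nt × 3,500 nt =
2.1 μm → 46.7-fold (printed "~50" at 1 s.f.).  The TREX copy estimate is
`n_sites × saturation / sites_per_complex` = 16 × 0.995 / 4 ≈ 3.98 with
four UAP56 per TREX; the raw value is primary and the commonly quoted
"two to three" band is not asserted, since no explicit formula connects
them.  Raw values are always primary; "as-printed" renderings (2 s.f.
concentrations, 1 s.f. fold) are separate convenience fields.  The nuclear
UAP56 copy number behind the 3.2 μM nucleoplasmic estimate is an input
from external measurements, not a claim of this package.

## Binding fits

Fraction bound is `retained / (retained + flowthrough)` of
background-corrected membrane signals (negative inputs clamp to 0 with a
warning).  `fit_hill` fits `Y = Bmax·X^h/(K_D^h + X^h)` by unweighted
nonlinear least squares (the emulated tool's default), Bmax constrained to
1 unless freed; K_D initializes at the concentration nearest half-max, h
at 1.  95% CIs use the asymptotic covariance with a Student-t critical
value at n − p residual degrees of freedom — the standard finite-sample
choice, and the one that brings simulated coverage into [0.90, 0.99] at
the study's design point (12 points, 2% noise).  Non-convergence is
reported via `converged=False`, never as a silent estimate.  Rescaling
concentrations rescales K_D identically and leaves h unchanged.

## Crosslink validation

Crosslinked residue pairs are evaluated as Euclidean Cα–Cα distances on a
coordinate model, flagged at a 30 Å cutoff, and histogrammed in 5 Å bins.
Residues absent from the model are tallied as "unmapped", not errors or
silent drops — real models have unmodelled regions.  The synthetic fixture
draws each link "long" (> cutoff on the model) with a configured
probability, so the violation count has binomial ground truth.

## Embedding

`embed_pairs` z-scores the 4-D descriptor (rotX, rotY, rotZ, center
distance) and delegates to scikit-learn's t-SNE (PCA init, fixed seed,
deterministic).  At least 3 × perplexity rows are required.  Note that
z-scoring makes separation visible only when it dominates every feature's
own spread; the positive-control construction (two `clustered`
`fixed-sites` scenes differing in twist and diameter) is designed to
satisfy that.

## Problem sizes and numerical choices

Simulation sizes used by the test suite and acceptance script — 2,000
pairs for the orientation null, 200 simulated binding curves, 1,000 Welch
null draws at group sizes 259/245, 300 contact pairs, 100 crosslinks —
were chosen once as the smallest sizes at which the targeted statistics
(KS at α = 0.01, median error, coverage, type-I rate, binomial closure)
are stable, and are fixed in the code.  Rotation validity is checked at
1e-6 orthonormality tolerance; Euler round trips are exact to ~1e-13
degrees; brentq places contact pairs to 1e-3 Å of the target gap.

## Limitations

Synthetic scenes idealize real tomograms: ellipsoidal particles, no
neighbour contacts, no imaging noise, exact poses with no alignment error,
and a complex model that is exactly C2-symmetric.  Passing tests therefore
demonstrate correctness of the measurement pipeline, not robustness to
experimental artefacts such as misassigned particles, missing-wedge
distortions, or pseudo-symmetric complexes.  Counts specific to the real
dataset (pair totals, observed contact fractions, measured K_Ds) require
the deposited data and published processing pipelines and are out of
scope; they are replaced by generator-ground-truth closure checks.
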