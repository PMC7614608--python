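# globulegeom

Quantitative analysis of TREX-coated mRNP globules, for structural
biologists working with subtomogram-averaging outputs.  Nuclear mRNAs are
packaged into compact, roughly spherical ribonucleoprotein "globules"
whose surfaces are decorated by the C2-symmetric TREX export complex.
Given per-particle poses (rotation + position of a reference structure),
tomographic densities, binding curves and crosslink lists, this package
answers the study-level questions: how are pairs of complexes on the same
globule arranged relative to one another, how big and how spherical are
the globules, how strongly does avidity drive complex recruitment, and are
observed crosslinks consistent with the model?

All inputs can be produced by a seeded synthetic-scene generator with
recorded ground truth, so the entire pipeline is testable offline.

## What it computes

**Pairwise pose geometry.**  For two poses A, B of a C2-symmetric complex
the relative rotation R = R_A⁻¹R_B has four symmetry-equivalent
representatives C2^α·R·C2^β.  The canonical one is chosen by matching the
symmetry-mate markers (the two THOC1 copies in the TREX case) that land
closest in space; descriptors per pair are the center-marker distance d,
closest-atom distance, intrinsic-XYZ Euler angles (rotX, rotY, rotZ) of
the canonical rotation, spherical angles (θ, φ) of the A→B vector in A's
frame, and a contact flag (closest atoms ≤ 10 Å).  Uniform-orientation
null and clustered positive controls, plus a t-SNE embedding of the
(rotX, rotY, rotZ, d) descriptor, support testing for orientation
preferences.

**Particle morphometry.**  Iso-surface blob measurement on voxel grids:
volume = voxels × voxel³ above threshold (26-connected), principal-axis
extents, sphericity = shortest/longest extent, diameter summaries, and
Welch two-group comparison.

**Occupancy model.**  Local ligand concentration c = n/(N_A·(4/3)π(d/2)³)
of n UBM sites in a globule-sized sphere; single-site saturation
L/(L + K_D); mRNA compaction = contour length / diameter; implied TREX
copies per mRNP.

**Binding fits.**  Filter-binding fraction bound and nonlinear
least-squares fits of Y = Bmax·X^h/(K_D^h + X^h) with Bmax constrained to
1, Student-t 95% confidence intervals.

**Crosslink validation.**  Cα–Cα distances of crosslinked residue pairs
on a coordinate model, classified at 30 Å, with unmapped residues tallied.

## Worked example

```sh
$ globule-geom occupancy
UBM sites per mRNP:        16
local UBM concentration:   556.8 uM  (~560 uM)
UBM-UAP56 saturation:      99.5 %
mRNA compaction:           46.7-fold  (~50-fold)
TREX copies (raw):         3.98  (~4)
```

A median spliced human mRNA (3,500 nt, 8 introns) carries 8 EJC-bound
ALYREF adaptors with two UAP56-binding motifs each: 16 sites confined to a
450 Å globule is a ~560 μM local concentration, so even a weak 2.9 μM
single-site interaction sits at 99.5% occupancy — avidity makes
recruitment essentially quantitative.  Fully stretched, that mRNA is
2.1 μm long, so the 450 Å globule represents ~50-fold compaction.

The full synthetic pipeline (simulate → pairs → morphology → occupancy):

```sh
$ globule-geom run --seed 3 --out demo_out
{
 "config_hash": "c6ad9ffea21a",
 "seed": 3,
 "n_particles": 20,
 "n_poses": 34,
 "n_pairs": 18,
 "n_ground_truth_pairs": 19,
 "n_contacts": 1,
 "n_blobs": 20
}
```

Twenty synthetic globules carry 34 complexes giving 19 ground-truth
within-particle pairs; the analysis path reports 18 because one pose pair
fell within the 100 Å duplicate cutoff and was collapsed, and 1 pair is in
atomic contact.  `demo_out/` contains the pose table (STAR + CSV), the
rendered density (MRC), per-pair and per-blob CSVs, and `summary.json`.

Library use mirrors the CLI:

```python
from globulegeom import (SceneConfig, default_rigid_model, generate_scene,
                         extract_pairs)

model = default_rigid_model()
scene = generate_scene(SceneConfig(n_particles=50, seed=1), model)
pairs = extract_pairs(scene.poses, scene.pose_particle_ids, model)
```

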