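# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `dispquant`.  The package measures rigid displacement of
labelled anatomical structures between two 3-D scans by region-restricted
signed closest-point distances, and validates the whole chain on synthetic
phantoms with known ground truth.

## Coordinate conventions

All geometry lives in one right-handed world frame in millimetres.  Volumes
are arrays indexed `[i, j, k]` along world x/y/z with voxel `(i, j, k)`
centred at `origin + (i, j, k) * spacing`.  Rigid transforms are
`p ↦ R(p − c) + c + t` with `R = Rz·Ry·Rx` from extrinsic x-y-z Euler
angles in degrees; serialised JSON states the convention.  T1 (the earlier
scan) is always the fixed reference frame; the registration result maps T2
geometry into it.  Meshes are in world mm; STL files carry a JSON sidecar
recording units, source label and a mesh checksum, since STL itself has no
metadata.

## Rigid superimposition

The transform between time points is recovered by maximising Mattes mutual
information (32 bins) over the cranial-base label of the fixed image — the
structure surgery leaves untouched — with SimpleITK's registration
framework: a 3-level multi-resolution pyramid (shrink 4/2/1, smoothing
2/1/0 voxels), regular-step gradient descent (500 iterations, minimum step
1e-5), 50 % random metric sampling with a fixed seed so runs are
deterministic, and up to two restarts from perturbed initialisations if the
optimizer exhausts its iterations.  Two robustness measures matter on
slab-like masks:

* **ROI cropping.**  Both volumes are cropped to the mask's bounding box
  (8 mm pad; the moving image gets a further 12 mm capture pad).  The
  metric only reads fixed-image samples inside the mask, so this does not
  change the optimum, only the cost.
* **Coarse exhaustive translation seeding.**  The MI landscape of a
  slab-shaped mask is a broad plateau (faces aligned) with a sharp peak
  where internal structure aligns; gradient descent started on the plateau
  can stall several millimetres off.  A deterministic grid search over
  integer 2-mm translations within the capture range, scored with the
  package's own histogram MI at coarse resolution, seeds the optimizer.
  With this, 20/20 random ±5° / ±5 mm phantom poses are recovered with
  median error 0.027 mm / 0.047° (maximum 0.16 mm) in ~4 s each on one CPU.

Non-convergence is reported on the result, never silently ignored; the
returned metadata records metric, optimizer, pyramid and sampling settings.
The reported `final_mi_bits` is computed over the mask dilated by three
voxels so the bone–air interface that actually drives the fit contributes.

Intensities are resampled trilinearly, label maps with nearest-neighbour.
Resampling to the working resolution (0.5 mm, emulating reformatting from
the 0.4 mm acquisition) preserves world extent within one voxel.

## Surface extraction

Each label is binarised and meshed by marching cubes at the 0.5 iso-level.
By default the binary mask is first anti-aliased with a Gaussian of 0.8
voxel sigma: raw binary marching cubes overestimates a 20-mm sphere's area
by ~9 % through staircase faceting, while the anti-aliased surface is
within 0.6 % — and, because the kernel is symmetric, axis-aligned flat
faces remain exactly in plane, so distances measured on flat phantom faces
are unaffected.  `smooth_sigma_voxels=0` restores the raw behaviour; no
mesh-level smoothing is ever applied.  Winding is normalised so normals
point out of the labelled solid (positive enclosed volume).

## Closest-point displacement

Distances are exact, not approximate.  A query against a target mesh is
answered by (1) an upper bound from the exact distance to the 8 triangles
with nearest centroids (KD-tree), (2) gathering every triangle whose
centroid lies within `bound + max triangle bounding radius` — a provably
sufficient candidate set — and (3) the exact point-to-triangle minimum
(Ericson's region decomposition, vectorised; face, edge and vertex cases)
over the candidates.  Equidistant triangles resolve to the lowest triangle
index, making results deterministic.  The test suite checks bit-level
agreement with an exhaustive all-triangles oracle.

The sign of a displacement is the sign of the dot product between
(closest point − vertex) and the vertex's outward normal, zero resolving
positive.  Regions whose signed values mix directions (negative fraction in
(0.05, 0.95)) trigger a warning: their signed mean underestimates the true
change — the reason curved nasal-base areas are unreliable for this kind of
analysis.

Painted regions are vertex patches: all vertices within a radius of the
seed's nearest vertex, under either euclidean or geodesic (edge-path
Dijkstra) distance, or an explicit vertex-id list for outline-following
patches.  A region records the checksum of the mesh it was painted on and
refuses to be applied to any other mesh; regions and meshes both carry
their anatomical label, and all queries are restricted to equal labels.
Region vertices live on the T1 mesh and query the registered T2 mesh by
default; a `direction` flag flips this, and the choice is recorded in every
output.

## Statistics

* **ICC(A,1)** — two-way, single-measurement, absolute-agreement intraclass
  correlation, computed from the ANOVA mean squares with the McGraw–Wong
  F-based 95 % CI.  Chosen because one operator measured everything twice
  and a systematic session offset should count against reliability; the
  model tag is printed in every report.  Duplicated sessions give exactly
  1; zero between-subject variance raises.  Cross-checked in tests against
  an independent OLS-ANOVA computation (1e-10) and against pingouin.
* **Paired differences** — per-area min/max/mean/SD of session differences
  with the t-based 95 % CI of the mean difference (the construction is a
  documented choice; the source format leaves it unstated).
* **Spearman** — average ranks for ties; for n ≤ 9 the two-sided p is exact
  by full enumeration of the n! rank permutations (cached null distribution
  in the tie-free case), since the asymptotic approximation is poor at
  n = 8; larger n uses the t approximation, and the switch is recorded.
* **Correlation matrices** — the maxillary set (9 areas) and mandibular set
  (6 areas), rendered with r below and p above the diagonal, significance
  at α = 0.05 per cell with no multiple-testing correction (matching the
  study design; a Holm adjustment exists behind `holm_adjust`, off by
  default).  The achieved type-I error of the matrix over null tables at
  n = 8 is verified to sit in [0.035, 0.065].

## The synthetic phantom

A subject is a set of axis-aligned primitives on a 176×208×208 grid at
0.5 mm (88 × 104 × 104 mm): a cranial-base slab, maxilla and mandible boxes
with flat anterior faces, and a 30-mm-thick facial soft-tissue slab.
Intensities are bone 1200, soft tissue 300, air 0, with additive Gaussian
noise (sd 30); the values are arbitrary — only their ordering matters to
MI.  The cranial base contains 14 air cavities ("sinuses", deterministic
per subject) because a featureless slab leaves in-plane translation almost
unconstrained by any intensity metric; real voxel-based superimposition
relies on exactly this kind of internal anatomy.

Surgery is a sagittal (anterior) translation per jaw.  The soft shell is
split by height into three rigid coupling zones: mandibular and maxillary
zones that move as `coupling × advancement` of their jaw plus a per-subject
isotropic jitter, and a nasal zone that only jitters — emulating the
clinical finding that nasal-tip change does not track maxillary
advancement.  A whole-head rigid nuisance pose (default ±2°, ±2 mm) is
applied to everything at T2.  T2 label maps are produced by per-piece
inverse nearest-neighbour resampling, intensities by sampling the noiseless
T1 field through each piece's transform plus fresh noise, so cavities move
rigidly with the base.  Jitter is drawn per zone and subject (not per
voxel/vertex): the measured quantity is a region mean, so per-vertex noise
would largely average out; per-subject jitter is what creates realistic
between-subject scatter for the correlation analysis.

**Geometric margins.**  True closest-point distance reads a pure
advancement only while every other same-label surface — the piece's own
posterior/side faces and the tears between soft-tissue zones — stays
farther from the painted area than the displacement itself.  Two
consequences shaped the defaults: pieces are deep (jaws 32 mm, shell 30 mm)
so an advancement can never get closer to the wrapped-around posterior
face than to the advanced anterior face, and the 15 default areas are
placed with in-plane margins exceeding the largest drawable displacement
(~15 mm).  The one deliberate exception is Lower Incisors, which sits near
the mandible's top edge and is attenuated (and for advancements beyond
~12 mm partially sign-scrambled by the perpendicular edge face) — the
analogue of the incisal areas that were the problematic ones in practice.
Nasal Tip mixes signs by construction; its sign-mixing warning is the
intended diagnostic.

Cohorts draw per-subject plans uniformly: maxillary advancement U[1, 5] mm,
mandibular U[5, 15] mm (the magnitude range reported for bimaxillary
advancement), soft/hard coupling U[0.7, 1.0], soft jitter sd 0.5 mm, head
pose ±2° / ±2 mm.  A draw whose pose pushes a piece outside the grid is
rejected and redrawn (up to 20 attempts), i.e. the plan distribution is
conditioned on geometric validity.  One integer seed reproduces a cohort
byte-for-byte.

**What the phantom does not model** — and hence what passing tests do not
show about real data: anatomical shape (condyles, curved faces), CBCT
physics (beam hardening, metal/bracket artifacts), soft-tissue deformation
(zones are rigid, so the shell "tears" at zone boundaries instead of
stretching), occlusion changes, or operator variability in painting areas
(the second measurement session is an exact duplicate by default;
`repeat_seed_jitter_mm` re-paints with perturbed seeds).

## Pipeline, determinism, problem sizes

`run_subject` executes resample → cranial-base registration → per-label
extraction → region measurement, failing with a stage-named error;
`run_cohort` tallies per-subject failures and assembles the four report
tables (repeatability, descriptives, two correlation matrices).  Every
output embeds a hash of the configuration; identical config + seed
reproduces identical CSV numbers (registration sampling is seeded).
Intermediate artifacts (transform JSON, STL pairs, summary CSV, provenance
JSON) are written per subject when an output directory is set.

Default problem sizes were chosen to keep a full 8-subject cohort run
around two minutes on one CPU: ~7.6 M voxel volumes, meshes of 10⁵–10⁶
triangles, ~100–800 vertices per painted region, 20-pose registration
sweeps, 1000-table null simulations for the type-I calibration.

## Known limitations

* Registration assumes the initial misalignment is within the coarse
  search's capture range (±12 mm, ±~5°); clinically larger pose changes
  would need a wider search.
* Geodesic painting uses shortest edge paths, an upper bound on true
  surface geodesics; adequate for patch selection, not for exact geodesic
  radii.
* The exact-permutation Spearman p is enumerated up to n = 9 (362 880
  permutations); beyond that the t approximation takes over.
* Areas painted near label edges or zone tears are attenuated or
  sign-mixed (see margins above); the sign-mixing warning flags the
  affected summaries but cannot repair them.
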