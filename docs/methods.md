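# Methods

`tractoprint` implements a comparative white-matter analysis chain —
connectivity-based parcellation, protocol-constrained probabilistic
tractography, connectivity blueprints and cross-brain KL-divergence
matching — and exercises it on synthetic fiber-orientation phantoms whose
ground truth is known by construction. This note records the models, the
parameters that matter, the numerical conventions, and the design choices
made where the design was genuinely open.

## Synthetic species phantoms

Each phantom is a cuboid brain on an isotropic grid (1 mm voxels): a
gray-matter shell of `gm_thickness` voxels (default 2) lines the grid
boundary, and everything inside is white matter. Bundles are tubes of
radius `radius_vox` around piecewise-linear centerlines; their end caps
reach the gray/white border, so the surface vertices over each cap carry
that bundle's label as ground truth. Bundle voxels store the local
centerline tangent, perturbed once at generation time by rotating it about
a uniformly random in-plane axis through a half-normal angle with standard
deviation `dispersion_deg` (default 10°) — a deliberately simple, isotropic
stand-in for a crossing-fiber posterior. Orientations are axial
(undirected) and stored with the first nonzero component positive.
Non-bundle white matter is flagged *isotropic*: samples drawn there are
uniform random directions, which makes off-tract tracking diffuse rather
than forbidden.

The gray/white surface is extracted with `skimage.measure.marching_cubes`
on the white-matter mask. We chose marching cubes over a hand-rolled
face-center construction because it is already available, produces a proper
triangulation with well-defined adjacency, and is deterministic; its
vertices lie within one voxel of the gray/white interface by construction.
Because the white-matter mask depends only on the grid and the shell
thickness — never on the bundles — all phantoms on the same grid share an
*identical* surface, and vertex homology across phantoms is the identity on
vertex indices. This is the ground truth the cross-brain matching analyses
rely on.

Cohorts model inter-subject variability by a rigid displacement of each
bundle's centerline, drawn per subject from a normal with scale
`subject_jitter_vox`, truncated at ±2 scales and projected perpendicular to
the bundle chord (so the end caps stay on the border and keep their surface
territory). Draws that would interpenetrate two tubes or push one off the
grid are rejected and redrawn deterministically — real tract anatomies
deform without overlapping — so the effective jitter distribution is the
truncated normal conditioned on anatomical validity. No quantitative inter-subject variability was available to
calibrate against; the default scales (0.75 voxels for the 36-voxel
comparison phantoms, 1.0 for the 40-voxel parcellation phantoms) are free
parameters chosen to displace tubes by roughly half their radius. A vertex
is labeled with a bundle if a tube voxel center lies within 1.5 voxels;
this includes a thin rim of vertices whose nearest white-matter voxel is
just outside the tube, which bounds the achievable fingerprint accuracy
below 100 %.

Two fixed geometries define the study conditions. The *three-bundle brain*
carries straight MdLF, IFOF and ILF tubes (radius 2) with the ILF running
directly alongside the IFOF (one-voxel gap), mirroring their adjacent
anatomical course. The *split brain* is identical except that the ILF
splits into a medial subcomponent congruent with the other brain's ILF
(still beside the IFOF) and a lateral subcomponent displaced 8 voxels away
from every other tract, plus an arcuate-like bundle (radius 2) that runs
dorsally and bends ventrally toward the posterior border. The adjacency
structure is load-bearing: it is what gives medial-ILF fingerprints their
small IFOF component and makes the lateral/medial swap comparison
directional. The parcellation phantom uses the same inventory on a
40-voxel grid with radius 2.5 and wider spacing.

## Streamline tractography

The tracker is a discrete Euler integrator. At each step the containing
voxel (`floor(position / voxel_size)`) is resolved — no trilinear
interpolation, for masks or orientations, so semantics on the coarse
phantom grids are exact — and the protocol is applied in a fixed order:
exclusion test (deletes the streamline, checked on every visited voxel
including the first), visitation recording, waypoint recording, termination
test (stops the streamline, kept). Then a direction is sampled:
probabilistic mode draws a stored orientation weight-proportionally and
re-perturbs it by the field's dispersion (same half-normal rotation as the
generator); deterministic mode takes the highest-weight orientation
unperturbed and stops at isotropic voxels. The sign is flipped to align
with the previous direction; if the aligned cosine falls below
`curvature_threshold` the streamline stops without taking the step.

Default parameters follow the reference protocol: 10,000 samples per seed
voxel, 2,000 steps, curvature threshold 0.2 (interpreted as the minimum
cosine between successive step directions), 0.5 mm steps. The phantom
analyses scale the sampling down (their values below); the step limit is
never binding there, as paths across a 36–40 voxel grid need at most ~90
steps of the 120–180 allowed.

Seeds sit in the tract body with waypoints on both sides, so streamlines
are unidirectional: half of each voxel's samples launch with each initial
orientation sign. Retention requires crossing at least one waypoint (OR
across waypoint masks); with no waypoint masks every non-excluded
streamline is retained (the unconstrained mode used for connectivity
matrices). Each retained streamline increments a voxel at most once, making
the normalized map (counts divided by the retained count) the probability
that a retained streamline visits the voxel. Deterministic mode starts at
voxel centers and consumes no randomness, so it is invariant across seeds.

**Randomness.** Every streamline `s` under root seed `S` owns the generator
`numpy.random.default_rng([S, s])` and consumes a fixed schedule — 3
uniforms for the start jitter inside the seed voxel, then exactly 4
uniforms per step (orientation choice, in-plane axis angle, half-normal
magnitude via the normal quantile, sphere z-coordinate; unused entries are
still consumed). The batch tracker therefore reproduces single-streamline
propagation bitwise, and an independently coded oracle can replay the exact
stream; the test suite does both.

## Connectivity-based parcellation

An ROI is a slab of three consecutive slices along the longitudinal axis,
restricted to tract-bearing white matter. Every ROI voxel seeds
unconstrained tracking (500 samples per voxel in the study runs) that
terminates at gray matter, giving an ROI-voxels × brain-voxels matrix of
binary-per-streamline visitation counts. The similarity matrix is the
Pearson correlation of connectivity rows — the source workflow says only
"similarity matrix"; correlation is the standard choice in
connectivity-based parcellation. Rows with zero variance get similarity 0
to all others (diagonal 1), and the matrix is made exactly symmetric.
k-means runs on the similarity rows (each voxel represented by its
similarity profile) with 50 k-means++ restarts and a fixed seed; labels are
canonicalized by descending cluster size, ties by lowest voxel index.

Clusters map to tracts by maximizing overlap with a reference label volume
(Hungarian assignment, ties to the lowest tract id, zero-overlap clusters
unassigned). The reference is the phantom's ground-truth labels — the
phantom stand-in for assigning clusters "from anatomical knowledge", which
has no synthetic equivalent. Across subjects, assigned clusters become
per-tract probability maps (fraction of subjects containing each voxel),
from which seed/waypoint masks are drawn: each tract takes its `n_voxels`
highest-probability voxels, voxels claimed by several tracts go to the
higher probability (ties to the lowest tract id) and losers move to their
next-best voxel, iterated to a fixed point. The result is equal-sized,
pairwise-disjoint masks by construction.

**Reliability statistics.** Dice between solutions is compared with a
1,000-permutation null obtained by permuting one solution's
voxel-to-cluster labels. The *hierarchy index* between a k and a k+1
solution assigns each k+1 cluster the k-cluster parent of maximal overlap
and reports the fraction of ROI voxels contained in their cluster's parent;
its null permutes the k+1 labels. This parent-containment formula is a
reconstruction — the original definition lives in supplementary material
not available to us — chosen because it is 1 exactly for perfect
refinements, lies in [0, 1], and is invariant under relabeling; it is
validated against those properties, not against the original.
Correspondence percentage is the Jaccard overlap × 100 and
cluster-transition tables report, per parent cluster, the percentage of its
voxels flowing to each child.

## Connectivity blueprints

The vertexwise connectivity matrix tracks from every surface vertex's
nearest white-matter voxel (96 samples per vertex in the study runs,
terminating at gray matter); vertices with no white matter within 2 voxels
keep a zero row. The blueprint is the product of this matrix with the
voxel × tract matrix of averaged normalized tractograms, row-normalized to
sum 1. Normalization to a probability distribution is asserted here because
the KL comparison requires it; rows that are identically zero stay zero and
carry an explicit *undefined* flag consumed downstream. We normalize before
any masking; normalizing after masking to a subregion would change nothing
because normalization is per-row.

Surface projections (per-tract columns of the raw product) are display
quantities; they reuse the volume display transform (log(1+v), scaled to
max 1) after smoothing. Surface smoothing is iterated symmetric graph
diffusion (`x_i += λ/d_max · Σ_j (x_j − x_i)`, λ = 0.5) run for as many
iterations as needed to accumulate the variance of a Gaussian with
sd = FWHM / 2.3548, estimated from the mean squared edge length. The
operator preserves constants exactly, conserves the total sum, and leaves
isolated vertices untouched; the iteration count is an approximation to a
true geodesic Gaussian, adequate for display and territory masking.

## Divergence comparison

KL divergence between fingerprints is computed in nats with a symmetric
pseudocount of 1e-8 added to both arguments (`Σ p_i ln((p_i+ε)/(q_i+ε))`;
terms with p_i = 0 contribute nothing). The source workflow states neither
the log base nor the zero-handling; the pseudocount bounds any single
absent-tract term by ln(1/ε) ≈ 18.4 nats. Min-KL maps take, per defined
vertex in one brain, the minimum over all defined vertices of the other
(ties to the lowest vertex id); undefined vertices are excluded from the
pool in both directions. Best-match fingerprints average the 10
lowest-divergence vertices. Distribution comparisons use only strictly
positive min-KL values and the two-sided two-sample Kolmogorov–Smirnov test
with the asymptotic p-value (sample sizes in use are in the hundreds), at
the pre-declared p < 0.01 level.

The ILF-swap comparison is a sign check, and its per-vertex signal is
small by design: it rests entirely on the IFOF admixture that tube
adjacency induces in medial-ILF fingerprints, and the territory's core
vertices are seeded deepest in the tube where that admixture is weakest.
The mean (lateral − medial) difference is positive across seeds but its
magnitude varies by two orders (≈1e-4 to 3e-2 nats).

**Territory definitions.** A tract's surface territory is, by default, the
display convention: vertices whose smoothed (2 mm FWHM), log-normalized
projection reaches 0.7. This is used for the ILF-swap comparison. For the
arcuate co-localization check we instead define the arcuate's territory by
fingerprint dominance — vertices whose own-brain fingerprint has its
maximum in the arcuate column. The projection convention under-weights
sparsely-seeded dorsal-wall vertices whose *relative* (normalized)
fingerprint is nonetheless purely arcuate: the arcuate sweeps 2 voxels
beneath the dorsal surface, so the cortex overlying its whole course — not
just its end caps — is genuinely arcuate-dominated (median arcuate
fingerprint mass 1.0 among elevated vertices; ~97 % of vertices within 4
voxels of the tube are elevated). Dominance is computed from the split
brain's own blueprint before any cross-brain comparison, so the check is
not circular. "Elevated" means exceeding the maximum min-KL observed
without the arcuate column.

## Study conditions and problem sizes

| analysis | grid | cohort | sampling | runtime (1 CPU) |
|---|---|---|---|---|
| parcellation, k=3 | 40³ | 4 subjects | 500/voxel, ≤180 steps | ~20 s |
| split parcellation, k=4 | 40³ | 1 subject | 500/voxel | ~7 s |
| blueprint comparison | 36³ | 3 subjects/species | tracts 200/voxel, vertices 96, ≤150 steps | ~85 s |
| identity comparison | 36³ | 2 subjects/side | same | ~50 s |

The identity comparison analyzes the *same* phantom twice with independent
tracking randomness, so its min-KL distribution isolates pure estimation
noise. The k=4 separation check uses one subject because separation is a
per-solution property. The arcuate protocol applied to the brain without an
arcuate retains no streamlines and yields an all-zero column (with a
warning) — the intended behavior for a tract probed in a brain that lacks
it.

## What the phantoms do and do not show

The generator reproduces the statistical structure the analyses assume:
multi-orientation voxels with angular dispersion, parallel and split
bundles with partial inter-subject overlap, a curved species-unique
bundle, a gray/white border surface with known vertex truth and known
cross-phantom homology. It does not simulate diffusion physics (no DWI
signal, b-values or scanner noise), gyrification, registration error,
partial-volume effects, or realistic crossing-fiber geometry; background
white matter is isotropic rather than structured. Passing tests therefore
demonstrate that the *analysis chain* is correct and sensitive under its
own assumptions — that k-means parcellation recovers known tract bodies,
that blueprints align with ground truth, that the divergence machinery
detects a bundle present in only one brain and resolves subcomponent
homology in the right direction — not that those conclusions transfer to
any particular real acquisition.

## Numerical conventions and degenerate inputs

Positions live in mm with voxel i spanning [i·vs, (i+1)·vs). Orientation
vectors are unit within 1e-9. Blueprint rows sum to 1 within 1e-9 or are
exactly zero. All-zero volumes pass through the display transform unchanged
with a warning; zero-retention tractograms yield all-zero normalized maps
with a warning; empty KL distributions warn and return empty samples.
k-means ties, assignment ties and min-KL ties all break deterministically
(size/index, lowest tract id, lowest vertex id). Every random draw in the
package descends from a single root seed through either the per-streamline
scheme above or SHA-256-derived sub-seeds (`study.derive_seed`), keeping
all seeds below 2³¹.
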