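# Methods

## The measurement problem

Sea urchin larvae build calcite spicules: rods a few micrometres thick that
start as a triradiate (three arms from one junction) and elongate by mineral
deposition at rod tips. Perturbing the regulators of this process (e.g. ROCK
inhibition) changes four things that can be read off a segmented µCT volume:
how much mineral there is (volume, surface area), how far the rods ran
(total skeleton length), how fat they are (thickness), and whether tip
dominance was lost (ectopic branches — extra tips and junctions).
`spiculometry` computes these per spicule, quantifies fluorescence region
ratios for the accompanying immunostains, and runs the cohort statistics.

## Morphometric definitions

For a binary spicule mask on an `(nz, ny, nx)` grid with voxel spacing
`(sz, sy, sx)` µm (axis order z, y, x everywhere; voxel-centre coordinate
convention, physical position = origin + index × spacing):

- **Volume** `V = N_fg · sz·sy·sx`.
- **Surface area**: marching-cubes isosurface at the 0.5 level of the mask,
  after Gaussian smoothing with σ = 0.8 voxels. The smoothing matters: a
  mesh of the raw binary mask follows the voxel staircase and overestimates
  a digitized ball's area by ~9%, while the smoothed mesh is within ~1–2%
  (voxel-face counting, also provided, overestimates smooth surfaces by up
  to ~1.5×). Areas of blocky objects (cubes) are exact only in
  `voxel_face` mode.
- **Skeleton**: homotopy-preserving 3D thinning (scikit-image) to a
  one-voxel-wide, 26-connected medial skeleton.
- **Skeleton graph**: voxel degree under 26-adjacency; degree-1 voxels are
  endpoints, 26-adjacent voxels of degree ≥ 3 merge into one junction node
  (representative voxel = cluster member nearest the centroid, ties broken
  by lowest (z, y, x)); branches are maximal degree-2 paths between node
  clusters. An isolated cycle gets an arbitrary "anchor" node carrying one
  closed branch; anchors are counted as neither tips nor junctions.
- **Spur pruning**: endpoint-terminated branches shorter than a cutoff are
  removed iteratively, re-thinning after each round so junction voxels
  absorbed by a removed spur cannot keep a dissolved junction alive. The
  default cutoff is 3 × the EDT value at the branch's junction-end node:
  classical thinning produces spurs on the order of the local radius, while
  genuine ectopic branches in this system are many radii long. A free rod
  (endpoint-to-endpoint) is never pruned.
- **Total length**: sum of branch lengths. Default mode `path` sums
  Euclidean steps between consecutive path voxels; mode `chord` takes the
  straight-line distance between branch end voxels. `chord` under-measures
  curved branches, which is why `path` is the default; the mode used is
  recorded in metadata.
- **Mean thickness**: the Euclidean distance transform of the mask (exact,
  anisotropy-aware, with the volume boundary treated as background via an
  implicit one-voxel pad) sampled at skeleton voxels. Each sample is the
  local radius; the reported `mean_thickness_um` doubles the mean
  (diameter), because "thickness" colloquially means diameter; `radius`
  mode is retained since the distance-to-surface definition literally
  yields a radius.
- **Tips / junctions**: endpoint and junction node counts of the pruned
  graph.

Anisotropic volumes (spacing ratio > 1.2) are resampled to the finest
spacing before thinning: the float mask is smoothed with a Gaussian of
0.8 isotropic-voxel physical width, linearly interpolated, and
re-thresholded at 0.5. Plain nearest-neighbour upsampling leaves staircase
surfaces that inflate skeleton path lengths by ~15–20%.

## Statistics

- One-sample z-test of a mean (typically a ratio) against µ₀:
  `z = (x̄ − µ₀)/(s/√n)`, sample sd (n−1), p from the standard normal.
- Paired t-test on differences, df = n−1.
- Kruskal–Wallis with mid-ranks and tie correction
  `H' = H / (1 − Σ(t³−t)/(N³−N))`, p via the χ² approximation (k−1 df);
  group sizes below 5 trigger a warning that the approximation is rough.
- Fold change = ratio of group means; growth rate = difference of group
  means divided by the time interval (µm³/hr for volume).
- No multiple-testing correction by default (matching the original
  reporting); Bonferroni is available and the choice is recorded in output
  metadata. These statistics are computed from their closed forms so that
  scipy's implementations remain available as independent cross-checks in
  the test suite.

## Synthetic phantoms and what they do (not) show

Phantoms are unions of capsules (cylinders with hemispherical caps)
rasterized by a voxel-centre point-in-capsule test. Capsules were chosen
because their medial axis is exactly the centerline segment, giving clean
analytic truth for length (Σ centerline lengths), volume
(πr²L + 4/3·πr³ per capsule; summed capsule volume is an upper bound for
multi-capsule phantoms, which overlap slightly at junctions), radius and
topology. Partial-volume effects are emulated only by the grayscale
renderer (Gaussian blur of the label map, then foreground/background mean
intensities 40000/10000 with Gaussian noise sd 2000, clipped 16-bit).

Branch phenotypes: a back branch attaches one side capsule at fraction
f < 1 along the rod; a tip split (f = 1) attaches two prongs at the rod end
(a single branch at the very end would be a corner with two tips and no
junction). Ground truth records the junction position so tests can require
the measured junction within 10 µm of the truth.

Cohorts draw per-spicule volumes Normal(mean, cv·mean) per
condition × timepoint group and realize them by scaling rod length at fixed
radius (4 µm), so thickness truth is constant within a cohort. The default
cohort reproduces the µCT study design: control vs ROCK-inhibited at 48 and
72 hpf, means chosen to give a 325.5 µm³/hr control growth rate, a
119.8 µm³/hr inhibited rate, and a 2.5-fold control/inhibited volume ratio
at 72 hpf (these three published constraints cannot hold simultaneously
with a 2.5-fold ratio at 48 hpf as well; the 48 hpf ratio implied by the
defaults is 2.30). Group size defaults to 40 with cv 0.2; ectopic branching
probability is 0 for control and 0.5 for the inhibited condition
(branching is essentially absent in control embryos and frequent under
inhibition). All randomness derives from one integer seed with per-phantom
sub-streams, so outputs are bit-identical across runs.

Fluorescence fixtures set an exact count of stained pixels per named region
(any threshold between the background and stained levels recovers them
exactly), or place non-overlapping circular blobs whose pixels are the
stained pixels (emulating calcein-stained vesicles). The preset region
ratios are the study's measured group means: skeletogenic/ectoderm ROCK
signal 1.3 / 1.8 / 4.6 at 22 / 27 / 33 hpf in controls, and a threefold
phalloidin tip/back enrichment.

What passing phantom tests does **not** show about real data: phantoms are
straight, constant-radius, noise-free-boundary objects; real spicules are
curved, varying in cross-section, and segmented from reconstruction
artifacts, so absolute accuracies on real scans will be worse than the
phantom tolerances, and surface areas depend on the meshing convention
(the original Amira measurement algorithm is not public).

## Numerical choices and degenerate inputs

- EDT is exact (scipy) and is tested against an O(n²) brute-force
  nearest-background search.
- 16-bit conversion: global min–max rescale to [0, 65535], round-half-up;
  constant volumes map to zero. Whether the original conversion was global
  or per-slice is unknown; global was chosen.
- Otsu thresholding is the automated stand-in for the original interactive
  segmentation; the optional seed mask reproduces the "user-augmented"
  step by keeping only marked components. Default minimum component size is
  100 voxels at 1 µm spacing, scaled by voxel volume.
- Foreground connectivity 26 with 6-connected background, the standard
  complementary pair.
- Degenerate cases: empty foreground, empty skeleton, zero-variance
  samples, zero-denominator ratios and unknown labels raise errors naming
  the problem; ratios with a zero denominator are excluded from downstream
  statistics with a log entry rather than imputed.
- Skeleton length is not exactly invariant under 90° grid rotations:
  thinning scan order can move an end voxel by one or two, and oblique rods
  lose up to ~one radius per end inside the rounded caps (observed ~2% for
  axis-aligned and up to ~10% for oblique rods). Volume and topology are
  exactly invariant.

## Problem sizes used in validation

The test-suite and acceptance-script simulations use: 200 random 12³
volumes for the EDT oracle; a single r=4 µm, L=100 µm capsule (~5300 µm³,
~107×15×15 voxels) for end-to-end recovery; cohorts of 40/group (the study
measured ~44/group) for fold-change recovery and 160/group for growth-rate
estimates; 200 replicate null cohorts for type-I calibration; and 33
simulated embryos per fluorescence group (the study's minimum group size).
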