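# Methods

This note records the models, conventions and numerical choices behind
`cabbage3d`, and what the synthetic benchmark does and does not establish.

## Canonical frame and normalization

All ten traits assume a canonical cloud: centroid at the origin, Z vertical,
unit scale.  The PCA correction maps the principal axis *most parallel to the
acquisition Z* to canonical Z rather than the largest-variance axis — a squat,
wide rosette has more horizontal than vertical variance, and height, the
projection planes and the axial slabs are all defined against the botanical
vertical, so verticality must survive the correction.  Signs are fixed
deterministically: the Z sign by a positive third moment of the projected z
(plants are top-heavy about their centroid in the canonical pose; an exactly
zero third moment leaves the sign unchanged), the X sign likewise, and Y by
right-handedness.  Degenerate (collinear) clouds are rejected.

Normalization divides by the Chebyshev extent (max |coordinate| after
centering), so every cloud fits the unit box.  Any fixed uniform scale would
do; this one is cheap, exact, and makes the size-bearing traits (W, V, S,
S1–S3, M) unit-free so that a trait table mixes plants of different absolute
size.  The ratio traits (T, θ̄, O) are scale-invariant regardless.  Note the
scale is referenced to the *centroid*, so a bottom-heavy plant normalizes
smaller than a symmetric one of the same bounding box — a property the
synthetic tight archetype exploits (below).

## Trait definitions and parameters

* `T`: max Z extent over max pairwise XY distance.  The spread is evaluated
  on XY convex-hull vertices, which equals the brute-force pairwise maximum
  (the diameter of a planar set is attained at hull vertices).
* `θ̄`: the plant is cut into three equal vertical slabs; the middle slab is
  statistically denoised (k=8, 2σ) and per-point unit normals are estimated
  by total-least-squares plane fits over `k_normals = 12` nearest neighbors
  (default chosen as a common neighborhood size for organ-scale normal
  estimation at a few thousand points per plant).  θᵢ = arccos|nᵢ·ẑ| in
  degrees, averaged over the slab; the absolute value folds both leaf faces
  onto [0°, 90°].
* `W`: the printed definition (max minus min pairwise distance over hull
  vertices) is self-contradictory in prose, so two modes exist: `literal`
  (default, the formula as printed) and `width` (rotating-calipers diameter
  minus width).  The literal minimum is dominated by adjacent hull vertices
  and therefore sensitive to outline density; the calipers mode is the
  robust alternative.  Both are tested; only the default participates in the
  pipeline.
* `V`, `S`: tetrahedron/triangle sums over the convex-hull triangulation
  (Qhull).  Volume terms are referenced to the hull centroid — a guaranteed
  interior point — so every |rᵢ·(rⱼ×rₖ)|/6 term is positive and the
  absolute-value sum equals the true volume.
* `S1–S3`: shoelace areas of the 2D hulls of the XZ/YZ/XY projections.  A
  degenerate projection (plant seen edge-on) yields area 0 with a warning
  rather than an error, because it is physically meaningful.
* `O`: XY hull area over the area of the exact minimum enclosing circle
  (Welzl-style incremental construction with a deterministic processing
  order; verified against a brute-force pair/triple search).
* `M`: main axis = first principal axis; `n_groups = 10` equal-thickness
  slabs along it ("several parts" is unstated upstream, 10 gives stable
  per-slab statistics at ≥1000 points); per-slab population variance (1/Sₖ,
  as printed) of point-to-axis distances, averaged over slabs with ≥2 points
  (sparser slabs are skipped with a warning).

Transformation laws (asserted at 1e-9 over random clouds): under uniform
scale s — T, θ̄, O invariant, W ∝ s, S/S1–S3/M ∝ s², V ∝ s³; under rigid
motions about Z — T, θ̄, O, W, V, S, S3, M invariant (S1/S2 are not, since
the side projections depend on the azimuth; their scaling law is asserted
under pure scaling).

## Type discovery

Traits are z-scored per column with the sample sd (ddof=1); constant columns
become zeros with a warning.  K-medoids is the literal Voronoi alternation:
assign to the nearest medoid (Euclidean on z-scores), re-elect each cluster's
medoid as the member minimizing summed intra-cluster distance, stop when
labels stabilize; best of 10 seeded restarts by total cost; every tie
(assignment, election, k selection) breaks toward the lowest index, making
the result a deterministic function of (data, k, seed).  PAM-style swap
search is deliberately not used — the Voronoi description is the specified
algorithm, and restarts compensate for local minima.  The cluster count is
chosen by the maximal silhouette over k = 2..8 computed from the K-medoids
labels; the k-means WCSS elbow is reported as a diagnostic only.

The four clusters are named by rank-sum rules frozen from the qualitative
type descriptions: TIGHT = minimal V+S3 rank-sum (compact, small footprint);
ROUND_SPREAD = maximal S3+O rank-sum among the rest (wide, round footprint);
of the remaining two, HIGHLY_LEAN has the larger T and FULL is last.  Ranks
are computed per trait column over the centroids; rank-sum ties break by the
rule's first criterion.  The published four-cluster centroid table is the
worked example: the rules reproduce its cluster-to-type naming exactly.

## Synthetic rosettes

A plant is `n_leaves` leaf patches around a vertical axis.  Each midrib is a
circular arc bending from vertical by `2·(90° − leaf_inclination)` in total
(so the mean surface normal sits near the target inclination); the blade
extends azimuthally with a mid-leaf width maximum and quadratic edge curl; a
fraction `heading_tightness` of leaves is short and upright (the head); the
cloud is squeezed in Y by `spread_anisotropy`, canonicalized into its PCA
frame, rescaled in Z to hit `height_spread_target`, jittered with Gaussian
noise (0.7% of spread), and colored in a green hue band (90–140°).

The four presets are engineered for *ordinal* fidelity of the canonical
traits, not photorealism: HIGHLY_LEAN has the largest T; TIGHT the smallest
V, S, S1–S3; ROUND_SPREAD the largest S3 and O; FULL the smallest T.  Two
structural devices secure the tight type's margins, because "tall and lean"
and "tight head" are intrinsic neighbors in normalized shape space: tight
gets three basal wrapper leaves that pin its spread while its head stays
thin (the XY hull becomes a small triangle rather than a filled disc), and a
strongly bottom-heavy mass profile (the centroid-referenced normalization
then shrinks it further).  The highly-lean preset is tall but girthy (wide
leaves, mild azimuthal asymmetry), which keeps its hull areas well above the
tight type's and separates the two classes on roundness and symmetry.
Per-sample variation draws each spec field from ±10% uniform ranges.

What the generator does *not* emulate: photogrammetric noise structure
(holes, ghost points, density falloff), soil/pot geometry, self-occlusion,
petiole/vein structure, growth stages.  Tests passing on these clouds show
the pipeline is correct and that the discovery/classification machinery
recovers planted structure at realistic noise levels — not that the specific
accuracy numbers transfer to field scans.

Augmentation (rotation 0–360° about Z, uniform scale 0.9–1.1, Gaussian noise
0.5% of the Z extent) mirrors standard test-set balancing for point-cloud
classifiers.

## Classifier

The encoder is the familiar set-abstraction hierarchy: FPS centroids,
radius-ball neighborhoods capped at `max_neighbors` (multi-scale grouping
concatenates branches over several radii), shared dense+ReLU layers per
point, max-pool per group; a final global stage pools into exactly 1024
features.  Two conventions make inference a pure function of the point set:
FPS starts at the point farthest from the centroid (geometric, so row order
cannot matter) and empty-ball padding repeats valid neighbors (harmless
under max-pooling).  The ten traits, z-scored with statistics from the
training split only, are concatenated after the global pool, so only the
fully connected head (input 1034) sees them; `use_traits=False` reproduces
the 1024-dim ablation.

Desk-scale defaults — 512 points, two local stages (64 and 16 centroids,
radii 0.3/0.7 on the unit-normalized cloud), global MLP 256→1024, head
128→4, dropout 0.5, Adam 1e-3 with 1e-4 weight decay, batch 8, 25 epochs —
train in about a minute per model on one CPU and are the configuration used
by the tests and the acceptance script.  The full-scale configuration (4096
points, multi-scale grouping, 200 epochs) is available via
`NetConfig.paper_scale()` but is not exercised by the default suite.
Training is seeded end to end (init, shuffling, dropout); the same seed
reproduces parameters bit-exactly, and serialization round-trips
predictions bit-exactly.

On the synthetic benchmark the 10 traits are themselves nearly sufficient
for classification, so the fused model's margin over the point-only model is
small (both are high); the asserted property is directional (fused ≥
point-only, fused ≥ 90% on held-out data), not a magnitude claim.

## Problem sizes

The default suite and the acceptance script use: 4 classes × 40 plants at
2000 points for type discovery (10 master seeds in the suite, 3 in the
script), 4 × 50 plants at 1200 points for the ablation (3 seeds in both), 512-point encoder inputs, and a single 25,000 →
20,000-point FPS run for the downsampling contract.  These sizes were chosen
so every stage's statistical behavior is visible while the whole pipeline
remains a desk-scale computation.

## Known limitations

* The sign conventions of the PCA frame rely on third moments; a perfectly
  symmetric plant's X/Y orientation is only pinned by floating-point noise.
* The literal `W` depends on hull-vertex density; use the `width` mode when
  comparing across very different point counts.
* θ̄ is a surface-normal statistic: it needs surface-sampled clouds, and on
  volumetric noise its plane fits are ill-conditioned.
* The Voronoi K-medoids finds local minima; 10 restarts are ample at n of a
  few hundred but k selection on weakly separated data remains noisy.
* The numpy network is CPU-bound and desk-scale; the paper-scale
  configuration is provided for completeness, not speed.
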