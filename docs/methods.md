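# Methods

`treeparse3d` segments individual trees out of plantation LiDAR point clouds
and extracts per-tree structural parameters. This note documents the models,
the numerical choices, and what the built-in synthetic data does and does
not establish.

## Problem setting

A UAV LiDAR survey of a row-planted stand (the motivating case is a rubber
plantation) yields an unordered set of 3D returns. Three properties make
individual-tree separation hard: adjacent crowns interpenetrate and form a
nearly continuous canopy surface; point density falls sharply from the
upper canopy to the trunks; and young and mature trees coexist, so no
single spatial scale fits all crowns. The pipeline addresses each property
with a dedicated stage.

## Multimodal deformable encoding (MDE)

Top-view crown outlines — LabelMe-style polygons digitized on a nadir
projection — carry boundary information that pure geometry lacks. The
encoder turns the polygon set into a fixed-length descriptor
(dimensionless: polygon count, area fractions of the annotated extent,
compactness statistics, coverage, centroid spread, class balance), projects
it to a semantic vector `F_s` (dimension `d_s`, default 64), and maps that
through an MLP to an 8 × `d_feat` *hypercube template* `H_s`. Each point's
normalized coordinates (x, y, z) ∈ [0,1]³ give trilinear weights over the
eight template vertices,

    w1 = (1−x)(1−y)(1−z), w2 = x(1−y)(1−z), …, w8 = xyz,

which sum to 1 exactly; the fused per-point feature is the weighted vertex
sum F_fused[n,·] = Σ_w W[n,w] H_s[w,·]. Downstream refinements: softmax
branch weights per point (combined as a weighted sum of per-branch scaled
views — the combination rule is this package's choice), a sigmoid sparse
gate over (coords, `F_s`) retaining points with score *strictly above*
`tau_g` (default 0.5), reorganization into 4 subspaces of width K = 16
whose second-moment matrices `Q_j = (1/N) Σ_i q_ij q_ijᵀ` (symmetric PSD)
summarize global structure, and a dynamic output kernel generated from the
gated subset combined with a linear coordinate residual. An empty gated
subset falls back to an identity-like kernel. The whole block is
deterministic given its seeded weights.

Two deliberate substitutions, flagged here because the original design is
not fully published: the sparse multi-scale U-Net between the JSON encoding
and fusion is replaced by a light 2-level refinement (mean-vertex context
mixed back through a linear layer), and the residual path projects raw
coordinates (the alternative — projecting prior features — is a
configuration away in code). The descriptor is scale-normalized because
raw areas/perimeters made the template depend on the physical block size,
which destroyed transfer between blocks.

## Z-order selective state-space block (ZOS-Mamba)

Points are voxelized (half-open bins, default 0.2 m), per-voxel features
are the mean of member points, and voxels are ordered by their Morton code
— bit i of x goes to output bit 3i, y to 3i+1, z to 3i+2 — with `b` the
minimal per-axis bit width covering the grid and stable tie-breaking. The
serialized sequence runs through a selective scan: input-dependent (Δ, B,
C) come from a seeded linear projection, Δ = Softplus(Δ̂) > 0, `A` is
initialized negative-diagonal (stable decay) and the feed-through `D` to 1.

The **sequential** mode evaluates

    x_t = exp(Δ_t A) x_{t−1} + Δ_t B_t u_t,   y_t = C_t x_t + D u_t

and is the correctness reference, tested against hand-unrolled recurrences.
The **parallel** mode evaluates the cumulative-sum form
`X = cumsum(exp(ΔA) ⊙ ΔB ⊙ u), y = CX + Du`. The two coincide when A = 0
and converge as ‖A‖ → 0, but the cumsum form is *not* algebraically equal
to the recurrence for general A (each term carries its own decay once,
without compounding); both are provided and the divergence is bounded in
tests rather than hidden. RMSNorm (`y / sqrt(mean(y²) + ε) ⊙ w`) follows
the scan; the inverse permutation restores spatial order and voxel features
are copied back to member points, so the point count is always preserved.

## Adaptive clustering (ALOC)

Instance separation runs on predicted-foreground points. A size-aware rule
picks the backend: below `size_threshold` (default 5 000) points, a
k-nearest-neighbor graph with edges above a merge distance removed
(connected components = instances, θ = (k, merge distance)); otherwise
MeanShift on the XY projection with θ = (bandwidth, minimum cluster size).
Mode seeking uses only upper-canopy "core" points — points within the top
30 % of their 1 m canopy-height cell — because crown tops stay separated
when crown skirts interlace, and the local threshold keeps young trees'
tops regardless of absolute height. All points are then assigned to the
nearest mode and undersized clusters merge into the nearest retained mode.

The hyperparameter search is a closed loop. A 5-point sweep across the
bounds box seeds the incumbent (the initialization is this package's
choice). Then, per iteration, the control factor
`E = 2 ln(1/u) · 2 arctan(1 − t/T)` decides the phase: Lévy-flight
exploration while E > 1 (step = u/|v|^{1/β}, β = 1.5, Mantegna scale
σ(1.5) ≈ 0.696575), and exploitation when E ≤ 1 — one of two contraction
updates toward the incumbent (picked with probability 0.5 each; their
perturbation terms are standard normal / uniform, as the distributions are
not published), optionally followed by a spiral step of amplitude
radius·(sin 2πr + cos 2πr) around the incumbent. Every candidate is clamped
to bounds. The candidate is scored by
`score = 0.7·mean(F1) + 0.3·max(F1)` over validation samples, and the
incumbent updates only on strict improvement, so the best score is
monotone; the walking state always moves to the candidate so the search
cannot stall at the incumbent fixed point. Search stops early at a
near-perfect score (0.999).

During supervised refinement the F1 values are instance F-scores against
labeled validation blocks. At pure inference time no labels exist; the
provided proxy objective (silhouette of the candidate clustering combined
with agreement between cluster count and canopy-height-model peak count)
is a clearly-labeled stand-in, not part of the published feedback rule.

## Semantic head and training

The two encoder blocks are deterministic feature extractors with seeded,
fixed weights; the trained component is a 2-layer MLP (hidden 32)
classifying crown vs background per point from the encoder features plus
seven geometric channels (normalized XY, height above block floor, raw z,
kNN radius, local z spread, height above the local ground cell). The loss
is class-balanced binary cross-entropy — canopy blocks are dominated by
crown points and an unweighted loss collapses to the majority prior — with
L2 weight decay (default 1e−3), optimized by Adam (default protocol:
150 epochs, batch of 16 blocks per step; gradients are derived by hand, the
model being small enough that no autodiff framework is warranted). Feature
standardization statistics are fit on the training set and frozen into the
checkpoint, batch-norm-style, so inference blocks are judged on the
training scale. Training is deterministic given the seed (per-epoch
shuffles are seeded by epoch index), which makes resumed runs bitwise equal
to uninterrupted ones. Instances come from ALOC on the thresholded
foreground (prob > 0.5); predicted instances below `min_instance_points`
(default 30) revert to background. Blocks are processed independently;
cross-block instance merging is deliberately not implemented (IDs are
offset per block).

## Synthetic plantation generator

The generator emulates the structural regimes above, not a physical LiDAR
simulator. Each tree is an ellipsoidal crown (vertical semi-axis 0.3 × the
tree height) over a thin cylindrical trunk reaching the crown center;
points are drawn uniformly inside each solid at Poisson counts
(canopy 25 pts/m³ vs trunk 2.5 pts/m³ by default — the 10:1 vertical
density contrast), a ground/understory layer is sampled at 40 pts/m²
(the realistic order for sub-canopy returns in a ~10⁴ pts/m² survey), one
deterministic apex return pins each treetop, and isotropic noise
(σ = 0.03 m) jitters every return. Layout is a rows × trees grid (defaults
7 m × 3 m, typical managed-rubber spacing) with small position jitter.
Crown radii are drawn from a range and capped at spacing/(2 − f) for
overlap factor f, so f = 0 guarantees disjoint crowns and interpenetration
is bounded at f·r. Growth stages: young trees at 0.5 × mature scale, mixed
30/70 by default, with an optional deterministic alternating layout for
fixtures that must contain both stages. Per-point labels (crown = 1,
background = 0; instance IDs for crowns), a per-tree ground-truth table
(position, height, analytic crown diameter and volume), and the paired
top-view JSON (convex hull of each instance's XY) come out together; one
seeded generator drives everything.

What the generator does **not** emulate: beam divergence, multi-echo
returns, occlusion shadows, terrain relief, understory vegetation
structure, or species-specific branch architecture. Passing tests
establish that the algorithms recover structure under the stated regimes
(overlap, density gradient, stage mixture); they do not certify field
accuracy on real scans.

## Evaluation conventions

Semantic quality is mIoU over {background, crown}; a class absent from
both maps is excluded (with a warning). Instance matching is greedy
one-to-one in descending point-set IoU with TP at IoU ≥ τ (default 0.5 —
the threshold is this package's default, not a published value); the
greedy choice is audited against a brute-force optimal assignment on small
cases and differs only in engineered ties. Precision, recall, F-score
follow the usual definitions with F = 0 when both are 0. AP integrates the
stepwise precision-recall curve by rectangle sums with predictions ranked
by confidence (mean foreground probability of the instance's points —
instance confidence is not defined in the source method).

## Structural parameters

Height = max z − ground (z = 0 plane for synthetic data, optional per-point
ground column otherwise). Crown diameter = 2·sqrt(hull area/π) of the crown
points' XY convex hull (an equal-area-circle convention; collinear and
two-point degenerate cases fall back to the max pairwise extent). Crown
volume = occupied-voxel volume at the configured voxel size (default
0.2 m); instances with fewer than 4 non-coplanar points report 0 with a
warning. Agreement against ground truth reports R² about the identity fit
(pred = truth, so R² can be negative and is NaN below 2 matched trees)
and RMSE, optionally per block.

## Problem sizes in the shipped checks

The test suite and acceptance script run everything at desk scale, chosen
as the smallest sizes that still exercise each regime: exhaustive Morton
verification on a 32³ grid; 10⁵-point partition-of-unity checks; clustering
recovery on 4 × 5-tree blocks (~15–20 k points) with a 50-iteration budget;
toy training on 8 trees in 3 blocks for 20 epochs with one block per Adam
step; structural parameters on noiseless 6-tree blocks at 60 pts/m³.

## Known limitations

- The encoders are randomly initialized and never trained; only the
  semantic head learns. The computational structure is faithful, but no
  claim is made about matching a trained model's representations.
- The parallel scan is the printed cumulative-sum form and intentionally
  not equivalent to the recurrence for general A (see above).
- LAS/LAZ I/O is not supported; convert to PLY/xyz upstream.
- The unsupervised clustering proxy can prefer a wrong granularity on
  canopies whose height model has spurious peaks; supervised feedback is
  always preferable when labels exist.
- Whole-scene block merging is a stub: blocks are independent and instance
  IDs are offset, with no cross-block association.
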