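# Methods

This note documents the models, parameters and numerical choices behind
`femurcut`, and what the synthetic validation does and does not show.

## Data model

All volumes live on a fixed internal axis order: array axis 0 = z (axial
slice direction), axis 1 = y (coronal), axis 2 = x (sagittal), with
per-axis spacing and origin in millimetres. SimpleITK's (x, y, z) metadata
order is converted at the I/O boundary (NIfTI, MetaImage/NRRD, DICOM
series). CT intensities are Hounsfield units exactly as stored (DICOM
rescale slope/intercept applied by the reader, nothing else), because the
body threshold is specified in HU. Masks serialize as unsigned 8-bit 0/1;
seed images as 0 = unlabelled, 1 = foreground, 2 = background. Every
downstream operation validates that its inputs share one grid
(shape + spacing + origin); NaN/Inf voxels are rejected at ingestion.

## Phase 1 — body ROI

Voxels strictly above −400 HU are kept; air (≈ −1000 HU) and scanner
padding values fall below any sensible threshold, so they need no special
casing. Two conventional cleanups follow, both optional flags: keep the
largest 6-connected component (removes couch and padding fragments) and
fill enclosed holes (internal gas pockets). Hole filling can reintroduce
sub-threshold voxels, so the "every ROI voxel is above threshold"
guarantee applies to the raw thresholded set, not the cleaned mask. The
ROI restricts the filter support, the regularizer average and the
graph-cut node set.

## Phase 2 — bone-and-joint enhancement

The local Hessian is obtained by convolving the CT with second and cross
derivatives of a Gaussian of physical scale `hessian_scale` (default
1.0 mm — on sub-millimetre in-plane CT this spans a cortical shell
without bridging the hip joint space; exposed as `--scale`). Anisotropic
voxels are handled by expressing the kernel sigma in voxels per axis and
the derivative in per-mm.

**Sub-voxel sigma correction.** With 3 mm slices the z-sigma is 0.33
voxels, where naively sampled Gaussian-derivative kernels lose their
vanishing moments: the raw second-derivative kernel then responds
strongly to *constants*, which saturates the filter everywhere. The
kernels used here are moment-normalized — zero response to constants (and
to linears, for order 2), unit response to the matching monomial — which
makes them exact on quadratics at any sigma and limits to the
central/second finite differences as sigma → 0.

Per voxel the eigenvalues are sorted by magnitude, |λ₃| ≥ |λ₂| ≥ |λ₁|,
and

    R_bones = |λ₁ λ₂| / λ₃²          (sheetness: 0 for sheets, → 1 for blobs)
    R_noise = (|λ₁|+|λ₂|+|λ₃|) / T   (structure strength vs. image average)
    BJE     = −sign(λ₃) · exp(−R²_bones/2) · (1 − exp(−4 R²_noise))

Since |λ₁|, |λ₂| ≤ |λ₃|, R_bones ∈ [0, 1]; both exponential factors lie
in [0, 1], so |BJE| ≤ 1 analytically. sign(0) = 0, so degenerate flat
voxels map to exactly 0; `1 − exp(·)` is evaluated via `expm1` for
accuracy at small arguments. The map is invariant under intensity shifts
(the Hessian kills constants) and under positive intensity scaling (both
ratios are homogeneous of degree zero, with T scaling along).

**The regularizer T** is "the mean absolute eigenvalue" statistic, which
admits two readings that differ by a factor 3: the mean over voxels of
the per-voxel *sum* |λ₁|+|λ₂|+|λ₃| (default, `t_convention="sum"`), or
the mean of all pooled individual eigenvalues (`"individual"`). The
averaging domain is the body ROI, not the padded volume — air would
dilute T and weaken noise suppression. A constant input (T = 0) yields an
all-zero map with a warning rather than an error.

## Phase 3 — seeded graph-cut

Seeds are an ordinary 8-bit label image painted in any viewer; counts of
each class are logged, and an absent class only warns (the segmentation
then rests on the unlabelled prior). The energy over binary labelings A,

    E(A) = Σ_p R(p) + λ Σ_{(p,q)∈N, p∈fg, q∈bg} B(p,q),

uses the per-voxel terms (R_f, R_b) = (λ, 0) / (1, λ) / (0, 1) for
foreground-seeded / background-seeded / unlabelled voxels, read as
terminal-link capacities: labelling a voxel foreground pays R_b, labelling
it background pays R_f, so λ-seeded voxels are near-hard constraints.
The literal "R as label cost" reading is available behind
`regional_as_capacity=False`. The unlabelled prior (0, 1) imposes a mild
one-per-voxel background bias; the boundary weight λ is what lets
boundary structure overcome it.

The boundary term is asymmetric — exponential when BJE descends from p to
q, λ otherwise — and is implemented as independent directed capacities
p→q and q→p. Cutting "downhill" across the sharp bright→dark edge at the
outer cortical surface is nearly free, while separating similar or
ascending neighbours costs λ (times the energy weight λ). Two
ambiguities of the original formulation are kept behind flags whose
defaults follow it literally: λ inside the exponent of B
(`lambda_in_exponent`, default on) and λ multiplying the boundary sum of
E (`lambda_in_energy`, default on). Defaults σ = 0.25, λ = 100,
6-connectivity (the smallest standard system; 18/26 available — the
joint-gap separation does not require diagonal links).

**Exact minimization.** The construction is submodular, so a minimum s-t
cut is a global optimum. Two backends: NetworkX (float capacities) for
small graphs, and `scipy.sparse.csgraph.maximum_flow` for image-size
grids. The scipy solver takes integer capacities, so capacities are
scaled by an adaptive fixed-point factor chosen so that the largest
capacity, any node's incident sum and the total flow all stay within
int32; the quantization step is ~10⁻⁴ of λ and affects at most
round-off-level tie-breaking. The cut partition is recovered by BFS on
the residual graph. `solver="auto"` switches backends at 2048 nodes.
Optimality is asserted in the tests against exhaustive enumeration on
3×3×1 instances for both backends and all dialect flags.

With an ROI, exterior voxels are forced background and excluded from the
graph; faces crossing the ROI boundary are not penalized (the energy is
that of the ROI subgraph). Ties between equal-energy cuts are resolved by
the solver; tests assert energies, not voxel identity, where ties are
possible. A largest-component cleanup (default on) stands in for the
interactive refinement step of the original workflow: it removes
localized spurious islands and nothing else.

## Metrics

DUR = 1 − |A∩B|/|A∪B| (Jaccard distance). HD and AHD are computed
between boundary-voxel sets (a mask voxel with a 6-neighbour outside the
mask), in millimetres via the exact Euclidean distance transform with the
grid spacing as sampling: the directed distance from A to B assigns each
surface voxel of A its distance to the nearest surface voxel of B; HD is
the max of the two directed maxima, AHD the mean of the two directed
means. An `all_voxels` surface mode exists and is recorded in the report.
A min-min directed reduction (the closest approach of the two surfaces)
is available as a documented curiosity only: it is not a distance between
shapes. Undefined cases raise explicitly (both masks empty for DUR, any
empty mask for HD/AHD).

## Consensus

Majority vote is foreground iff strictly more than half the raters agree,
with an explicit tie rule for even counts. STAPLE treats the hidden truth
and per-rater sensitivity/specificity (p_j, q_j) as unknowns of a
voxel-independent binary mixture with a fixed global foreground prior
(default: mean rater foreground fraction) and alternates posterior
computation (E) with performance re-estimation (M), in log space, until
the posterior stabilizes (tol 10⁻⁶, max 100 iterations). p_j and q_j are
clamped to (ε, 1−ε) to survive empty/full raters; the representative
mask thresholds the posterior at 0.5 (exposed). The EM log-likelihood
trajectory is returned and non-decrease is asserted in the tests;
SimpleITK's STAPLE filter serves as an independent cross-check of the
thresholded consensus. With exactly two complementary raters the model is
label-symmetric and the consensus may follow either reading; the
guarantees are that estimates match the confusion matrix against the
converged consensus and that the two raters cannot both be rated good.

## Synthetic phantom

The phantom emulates what makes hip CT hard, not femoral anatomy: a
sphere-plus-cylinder "femur" wrapped in a 1.5 mm cortical shell
(1200 HU) around a trabecular interior (250 HU), facing a solid
acetabular block (1000 HU) carved out by a sphere of radius head +
`joint_gap_mm`, inside a soft-tissue body (40 HU) surrounded by air
(−1000 HU). Default grid 96×96×48 voxels at 0.7×0.7×3.0 mm and default
noise 30 HU mirror clinical hip protocols; the joint gap defaults to
1.4 mm = 2 in-plane voxels. The acetabular block covers only the
equatorial band of the head (|z − z_head| ≤ 6 mm): at 3 mm slice
thickness a z-normal gap is physically erased by partial volume, so the
controlled adversarial geometry — a gap the pipeline must not bridge —
is kept in-plane, where it is resolvable. Partial volume is simulated by
rendering geometry and HU at 2× resolution and box-averaging down;
Gaussian noise is added last; truth masks are occupancy-majority at the
final grid. Everything is deterministic given `rng_seed`.

The synthetic operator (`synth_seeds`) paints all voxels at least
`erosion_mm` (default 2 mm) inside the truth on a few evenly spread
axial slices (default 3) as foreground, and voxels at least as far
outside it on the same slices as background, optionally restricted to
the body — mimicking generous, imprecise slice painting.

**What passing shows and does not show.** Phantom recovery (DUR ≤ 0.2,
zero pelvis overlap across seeds) demonstrates that the filter/cut
machinery resolves a thin in-plane gap under realistic noise and
anisotropy. The phantom has homogeneous tissue classes, a smooth convex
joint, no trabecular texture, no osteoporotic cortical thinning and no
kissing osteophytes; clinical performance on pathological hips is not
implied and in the original setting required an operator's refinement
pass.

## Problem sizes and runtimes

Unit tests use a coarsened phantom (24×40×52 at 3×1×1 mm, ~0.2 s per
pipeline run); recovery and acceptance checks run the full default grid
(~442k voxels, ~2 s per run, about half of it in the max-flow solve).
The acceptance script scans ~7.7M voxels of boneness output in ~10 s.

## Known limitations

- Single Hessian scale (no multi-scale maximum); the default 1.0 mm is a
  judgement call, not a fitted value.
- Binary labels only (femur vs. everything); no multi-bone output.
- The scipy max-flow backend quantizes capacities (int32); exact-energy
  work should use the NetworkX backend, as the tests do.
- DICOM ingestion reads one series per directory and relies on GDCM for
  slice ordering; no multi-series disambiguation.
- STAPLE uses a global scalar prior (no spatially varying prior / MRF
  extension).
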