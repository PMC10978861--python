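# femurcut

Semi-automated, unsupervised femur segmentation from CT volumes, with the
evaluation machinery to validate it: segmentation-comparison metrics,
consensus fusion of repeated segmentations, and a synthetic CT phantom
generator with known ground truth.

## The problem

Building a patient-specific finite-element model of the proximal femur
starts from segmenting the femur in a clinical CT. The thin hip joint
space (about a millimetre of soft-tissue intensity between the femoral
head and the acetabulum) suffers heavy partial-volume blurring at clinical
resolution, so naive thresholding merges femur and pelvis, and manual
segmentation is slow and operator-dependent. `femurcut` implements a
three-phase pipeline that needs only a few sparsely painted slices from an
operator and no training data:

1. **Body ROI** — keep voxels above −400 HU (drops air and padding), then
   largest component + hole filling.
2. **Bone-and-joint enhancement (BJE)** — from the eigenvalues of the
   Gaussian-scale Hessian, |λ₃| ≥ |λ₂| ≥ |λ₁|, compute per voxel

   BJE(p) = −sign(λ₃) · exp(−R²_bones/2) · (1 − exp(−4 R²_noise)),

   with R_bones = |λ₁λ₂|/λ₃² and R_noise = (|λ₁|+|λ₂|+|λ₃|)/T, where T is
   the mean absolute-eigenvalue sum over the ROI. The resulting *boneness
   map* lies in [−1, 1]: bright sheets (cortical bone) → +1, dark sheets
   (joint space) → −1, blobs and noise → 0.
3. **Seeded graph-cut** — minimize, exactly, by min-cut/max-flow,

   E(A) = Σ_p R(p) + λ Σ_{(p,q)∈N} B(p,q),

   where the per-voxel term R encodes operator seeds (foreground seed:
   (R_f, R_b) = (λ, 0); background: (1, λ); unlabelled: (0, 1)) and the
   boundary term B(p,q) = exp(−λ(BJE(p)−BJE(q))²/2σ²) if BJE(p) > BJE(q),
   else λ, makes cutting across a sharp bright→dark transition nearly
   free. Defaults: σ = 0.25, λ = 100, 6-connectivity.

Also included: **DUR** (Jaccard distance), **HD** and **AHD** (worst-case
and average symmetric surface distance, mm) for comparing binary
segmentations; **majority vote** and **STAPLE** (EM estimation of a
consensus plus per-rater sensitivity/specificity) for fusing repeated
segmentations.

## Worked example

```bash
python examples/segment_phantom.py
```

```
phantom femur: 18632 voxels; seeds: 544 fg / 16626 bg
segmented femur: 19016 voxels
DUR (Jaccard distance) vs truth: 0.065   # 0 = perfect overlap, 1 = disjoint
HD 9.27 mm, AHD 0.439 mm   # worst-case and average surface distances
voxels shared with the adjacent pelvis: 0   # 0 = the thin joint gap was respected
```

A synthetic hip CT (0.7×0.7 mm pixels, 3 mm slices, 1.4 mm joint gap,
30 HU noise) is segmented from three painted slices; the result overlaps
the generative femur truth to DUR 0.065 with an average surface error
under half a millimetre, and not a single voxel leaks across the joint
gap into the pelvis. The other scripts in `examples/` demonstrate the
boneness map, the metrics on repeated runs, and STAPLE parameter
recovery, each printing a line on what its numbers mean.

The same pipeline is available as a CLI for file-based workflows:

```bash
femurcut phantom --seed 1 --outdir ph/
femurcut segment --input ph/volume.nii.gz --seeds ph/seeds.nii.gz --output femur.nii.gz
femurcut metrics --a femur.nii.gz --b ph/femur_truth.nii.gz
```

Every `segment`/`run` invocation writes a `*.provenance.json` sidecar with
all parameters, the package version and input checksums; reruns are
bit-exact.

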