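"""Full pipeline on a synthetic hip phantom with known ground truth.

Generates a CT-like volume (bright cortical shell, trabecular interior,
adjacent pelvis across a 1.4 mm joint gap, 30 HU noise), paints sparse
operator-style seeds on three axial slices, runs body-ROI extraction, the
bone-and-joint enhancement filter and the seeded graph-cut, then scores
the result against the generative truth.
"""

import femurcut as fc

phantom = fc.generate(fc.PhantomSpec(rng_seed=1))
seeds = fc.synth_seeds(phantom.femur_truth, n_slices=3, rng_seed=1,
                       within=phantom.body_truth)
print(f"phantom femur: {phantom.femur_truth.count()} voxels; "
      f"seeds: {int(seeds.foreground.sum())} fg / {int(seeds.background.sum())} bg")

result = fc.segment_volume(phantom.volume, seeds)

report = fc.compare(result.mask, phantom.femur_truth)
overlap = int((result.mask.data & phantom.other_bone_truth.data).sum())
print(f"segmented femur: {result.mask.count()} voxels")
print(f"DUR (Jaccard distance) vs truth: {report.dur:.3f}   "
      "# 0 = perfect overlap, 1 = disjoint")
print(f"HD {report.hd_mm:.2f} mm, AHD {report.ahd_mm:.3f} mm   "
      "# worst-case and average surface distances")
print(f"voxels shared with the adjacent pelvis: {overlap}   "
      "# 0 = the thin joint gap was respected")
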