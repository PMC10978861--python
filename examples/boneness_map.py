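"""The bone-and-joint enhancement (BJE) filter on a phantom CT.

The filter maps Hounsfield units to a boneness score in [-1, 1] from the
local Hessian eigenvalues: bright sheet-like structure (cortical bone)
scores near +1, dark sheet-like structure (the joint space) near -1, and
blobs/noise are suppressed toward 0.
"""

import numpy as np
from scipy import ndimage

import femurcut as fc

phantom = fc.generate(fc.PhantomSpec(rng_seed=0))
roi = fc.segment_body(phantom.volume).mask
bje = fc.bje_map(phantom.volume, fc.BonenessParams(hessian_scale=1.0, roi=roi))

femur = phantom.femur_truth.data
shell = femur & ~ndimage.binary_erosion(femur, iterations=2)
gap = (ndimage.binary_dilation(femur, iterations=2)
       & ndimage.binary_dilation(phantom.other_bone_truth.data, iterations=2)
       & ~femur & ~phantom.other_bone_truth.data)
soft = phantom.body_truth.data & ~ndimage.binary_dilation(
    femur | phantom.other_bone_truth.data, iterations=4)

print(f"boneness range: [{bje.data.min():.3f}, {bje.data.max():.3f}]")
for name, mask in [("cortical shell", shell), ("joint gap", gap),
                   ("soft tissue", soft)]:
    med = float(np.median(bje.data[mask]))
    print(f"median boneness in {name:14s}: {med:+.3f}")
print("# shell -> +1, gap -> negative, soft tissue -> near 0: the contrast")
print("# the graph-cut needs to separate femur from pelvis.")
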