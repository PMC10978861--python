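"""Segmentation-comparison metrics in physical units.

Three measures are provided for a pair of binary segmentations A, B on a
shared grid:

* DUR (difference union ratio, the Jaccard distance):
  ``1 - |A ∩ B| / |A ∪ B|`` — a volume-overlap measure in [0, 1].
* HD (Hausdorff distance, mm): the larger of the two directed worst-case
  surface distances, ``max_a min_b d(a, b)`` — sensitive to isolated,
  localized errors.
* AHD (average Hausdorff distance, mm): the mean of the two directed
  *mean* surface distances — robust against isolated error peaks.

Distances are Euclidean in millimetres (spacing-aware) between boundary
voxels (a mask voxel with at least one 6-neighbour outside the mask);
``surface_mode="all_voxels"`` measures between full voxel sets instead.
Both directed distances reduce with sup-inf by default; a min-min variant
(``directed_reduction="min"``), which collapses to the closest approach of
the two surfaces, exists only as a documented curiosity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryMask

__all__ = ["MetricReport", "dur", "hausdorff", "compare"]

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclass
class MetricReport:
    dur: float
    hd_mm: float
    ahd_mm: float
    surface_mode: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.dur <= 1.0):
            raise ValueError(f"DUR out of [0, 1]: {self.dur}")
        if self.ahd_mm > self.hd_mm + 1e-12:
            raise ValueError(f"AHD {self.ahd_mm} exceeds HD {self.hd_mm}")

    def as_dict(self) -> dict:
        return {"dur": self.dur, "hd_mm": self.hd_mm, "ahd_mm": self.ahd_mm,
                "surface_mode": self.surface_mode}


def _check_pair(a: BinaryMask, b: BinaryMask) -> None:
    a.require_same_grid(b, "second mask")


def dur(a: BinaryMask, b: BinaryMask) -> float:
    """Difference union ratio (Jaccard distance) of two masks."""
    _check_pair(a, b)
    inter = int((a.data & b.data).sum())
    union = int((a.data | b.data).sum())
    if union == 0:
        raise ValueError("DUR undefined: both masks are empty")
    return (union - inter) / union


def _surface(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCTURE,
                                    border_value=0)
    return mask & ~eroded


def hausdorff(a: BinaryMask, b: BinaryMask,
              surface_mode: str = "boundary_voxels",
              directed_reduction: str = "max") -> tuple[float, float]:
    """(HD, AHD) in mm between two nonempty masks.

    The directed distance from A to B assigns each surface point of A its
    Euclidean distance to the nearest surface point of B; HD is the max of
    the two directed maxima and AHD the mean of the two directed means.
    Distance fields come from an exact Euclidean distance transform with
    the grid spacing as sampling, so anisotropic voxels are handled.
    """
    _check_pair(a, b)
    if surface_mode not in ("boundary_voxels", "all_voxels"):
        raise ValueError(f"unknown surface_mode {surface_mode!r}")
    if directed_reduction not in ("max", "min"):
        raise ValueError(f"unknown directed_reduction {directed_reduction!r}")
    if not a.data.any() or not b.data.any():
        raise ValueError("Hausdorff distance undefined for an empty mask")
    if surface_mode == "boundary_voxels":
        pa, pb = _surface(a.data), _surface(b.data)
    else:
        pa, pb = a.data, b.data
    spacing = a.spacing
    d_to_b = ndimage.distance_transform_edt(~pb, sampling=spacing)
    d_to_a = ndimage.distance_transform_edt(~pa, sampling=spacing)
    e_ab = d_to_b[pa]
    e_ba = d_to_a[pb]
    reduce = np.max if directed_reduction == "max" else np.min
    hd = float(max(reduce(e_ab), reduce(e_ba)))
    ahd = float((e_ab.mean() + e_ba.mean()) / 2.0)
    return hd, ahd


def compare(a: BinaryMask, b: BinaryMask,
            surface_mode: str = "boundary_voxels") -> MetricReport:
    """All three metrics as one report."""
    hd, ahd = hausdorff(a, b, surface_mode=surface_mode)
    return MetricReport(dur=dur(a, b), hd_mm=hd, ahd_mm=ahd,
                        surface_mode=surface_mode)
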