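"""Synthetic CT phantoms of a proximal femur with known ground truth.

The phantom emulates the geometry that makes hip CT segmentation hard: a
bright, thin cortical shell around a moderate trabecular interior, and an
adjacent concave "acetabulum" separated from the femoral head by a
millimetre-scale joint gap at soft-tissue intensity.  The stylized anatomy
is a sphere (femoral head) fused with a vertical cylinder (shaft), both
wrapped in a cortical shell, facing a bone block carved out by a sphere of
radius ``head + joint_gap`` — so the minimum femur/pelvis distance equals
the prescribed gap, with the closest approach oriented in-plane where the
CT resolution is finest.

Partial-volume blur is simulated physically: geometry and HU are rendered
on a grid ``supersample`` times finer and box-averaged down to the target
grid, so voxels straddling interfaces carry mixed intensities exactly as a
finite CT point-spread does to first order.  Additive Gaussian noise (HU)
is applied last.  Truth masks are occupancy-majority (>= 0.5) at the final
resolution.

Default acquisition geometry mirrors clinical hip CT protocols: 0.7 mm
in-plane spacing, 3.0 mm slices, on a 96 x 96 x 48 voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, ImageVolume

__all__ = ["FemurGeometry", "PhantomSpec", "PhantomData", "generate"]


@dataclass
class FemurGeometry:
    """Stylized proximal femur: sphere head + cylinder shaft + cortical shell."""

    shaft_radius_mm: float = 8.0
    head_radius_mm: float = 12.0
    cortical_thickness_mm: float = 1.5
    cortical_hu: float = 1200.0
    trabecular_hu: float = 250.0


@dataclass
class PhantomSpec:
    """Full phantom description; defaults are the reference study conditions.

    ``shape`` and ``spacing`` are in array order (z, y, x), spacing in mm.
    """

    shape: tuple[int, int, int] = (48, 96, 96)
    spacing: tuple[float, float, float] = (3.0, 0.7, 0.7)
    femur: FemurGeometry = field(default_factory=FemurGeometry)
    pelvis_offset_mm: float = 4.0     # medial overhang of the pelvis past the head centre
    pelvis_hu: float = 1000.0
    joint_gap_mm: float = 1.4
    soft_tissue_hu: float = 40.0
    air_hu: float = -1000.0
    noise_sd_hu: float = 30.0
    rng_seed: int = 0
    supersample: int = 2

    def __post_init__(self) -> None:
        if self.joint_gap_mm <= 0:
            raise ValueError("joint_gap_mm must be > 0")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        f = self.femur
        if not (f.cortical_hu > f.trabecular_hu > self.soft_tissue_hu > self.air_hu):
            raise ValueError(
                "HU ordering violated: need cortical > trabecular > soft tissue > air"
            )


@dataclass
class PhantomData:
    volume: ImageVolume
    femur_truth: BinaryMask
    other_bone_truth: BinaryMask
    body_truth: BinaryMask

    def __iter__(self):
        return iter((self.volume, self.femur_truth,
                     self.other_bone_truth, self.body_truth))


def _downsample_mean(arr: np.ndarray, ss: int) -> np.ndarray:
    if ss == 1:
        return arr
    nz, ny, nx = (s // ss for s in arr.shape)
    return arr.reshape(nz, ss, ny, ss, nx, ss).mean(axis=(1, 3, 5))


def generate(spec: PhantomSpec | None = None) -> PhantomData:
    """Render the phantom; deterministic given ``spec.rng_seed``.

    Returns the noisy HU volume plus femur / adjacent-bone / body truth
    masks on the same grid.

    Raises
    ------
    ValueError
        If the bone geometry does not fit inside the body outline on the
        requested grid (the message states the minimum physical extent).
    """
    if spec is None:
        spec = PhantomSpec()
    ss = spec.supersample
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing
    lz, ly, lx = nz * sz, ny * sy, nx * sx
    f = spec.femur

    # Physical layout (mm), anchored at the grid centre in-plane.
    cy, cx = ly / 2.0, lx / 2.0
    air_margin = 3.0
    body_by, body_bx = ly / 2.0 - air_margin, lx / 2.0 - air_margin
    head_c = np.array([0.70 * lz, cy, cx - 6.0])        # (z, y, x)
    shaft_c = (cy, cx + 4.0)
    gap_r = f.head_radius_mm + spec.joint_gap_mm

    # Fit check: bone content must stay >= 2 mm inside the body ellipse.
    need_x = max(abs(head_c[2] - cx) + gap_r,
                 abs(shaft_c[1] - cx) + f.shaft_radius_mm) + 2.0
    need_y = max(f.head_radius_mm + spec.joint_gap_mm, f.shaft_radius_mm) + 2.0
    need_z = lz - head_c[0] + 1.0
    if need_x > body_bx or need_y > body_by or need_z < 0:
        min_nx = int(np.ceil(2 * (need_x + air_margin) / sx))
        min_ny = int(np.ceil(2 * (need_y + air_margin) / sy))
        raise ValueError(
            f"phantom geometry does not fit the grid: need at least "
            f"(ny, nx) = ({min_ny}, {min_nx}) voxels at spacing "
            f"({sy}, {sx}) mm"
        )

    # Supersampled voxel-centre coordinates.
    ss_spacing = (sz / ss, sy / ss, sx / ss)
    z = (np.arange(nz * ss) + 0.5) * ss_spacing[0]
    y = (np.arange(ny * ss) + 0.5) * ss_spacing[1]
    x = (np.arange(nx * ss) + 0.5) * ss_spacing[2]
    zz = z[:, None, None]
    yy = y[None, :, None]
    xx = x[None, None, :]

    full_shape = (nz * ss, ny * ss, nx * ss)
    body = np.broadcast_to(
        (((yy - cy) / body_by) ** 2 + ((xx - cx) / body_bx) ** 2) <= 1.0,
        full_shape,
    ).copy()
    d_head2 = (zz - head_c[0]) ** 2 + (yy - head_c[1]) ** 2 + (xx - head_c[2]) ** 2
    head = d_head2 <= f.head_radius_mm ** 2
    shaft = (((yy - shaft_c[0]) ** 2 + (xx - shaft_c[1]) ** 2)
             <= f.shaft_radius_mm ** 2) & (zz <= head_c[0])
    femur = head | shaft
    # The acetabular block faces the equatorial band of the head only: at
    # multi-mm slice thickness a z-normal gap (acetabular roof) is erased by
    # partial volume, so the controlled thin-gap geometry is kept in-plane.
    pelvis = ((xx <= head_c[2] + spec.pelvis_offset_mm)
              & (np.abs(zz - head_c[0]) <= 6.0)
              & (d_head2 > gap_r ** 2)
              & body)
    femur &= body
    pelvis &= ~femur

    # Cortical shell: within cortical_thickness of the femur surface.
    d_in = ndimage.distance_transform_edt(femur, sampling=ss_spacing)
    shell = femur & (d_in <= f.cortical_thickness_mm)

    hu = np.full(femur.shape, spec.air_hu, dtype=np.float64)
    hu[body] = spec.soft_tissue_hu
    hu[pelvis] = spec.pelvis_hu
    hu[femur] = f.trabecular_hu
    hu[shell] = f.cortical_hu

    data = _downsample_mean(hu, ss)
    femur_truth = _downsample_mean(femur.astype(np.float64), ss) >= 0.5
    pelvis_truth = _downsample_mean(pelvis.astype(np.float64), ss) >= 0.5
    body_truth = _downsample_mean(body.astype(np.float64), ss) >= 0.5
    pelvis_truth &= ~femur_truth  # majority rounding must never overlap

    rng = np.random.default_rng(spec.rng_seed)
    if spec.noise_sd_hu > 0:
        data = data + rng.normal(0.0, spec.noise_sd_hu, size=data.shape)

    vol = ImageVolume(data=data, spacing=spec.spacing)
    return PhantomData(
        volume=vol,
        femur_truth=BinaryMask.like(vol, femur_truth),
        other_bone_truth=BinaryMask.like(vol, pelvis_truth),
        body_truth=BinaryMask.like(vol, body_truth),
    )
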