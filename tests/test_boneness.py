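import numpy as np
import pytest

import femurcut as fc
from femurcut.boneness import (
    BonenessParams,
    bje_from_eigenvalues,
    bje_map,
    hessian_eigenvalues,
    regularizer_t,
)

ANISO = (3.0, 0.7, 0.7)


def test_constant_volume_zero_eigenvalues():
    vol = fc.ImageVolume(np.full((8, 10, 12), 137.0), ANISO)
    eig = hessian_eigenvalues(vol, BonenessParams())
    for lam in (eig.lambda1, eig.lambda2, eig.lambda3):
        assert np.abs(lam).max() < 1e-10


@pytest.mark.parametrize("axis", [0, 1, 2])
def test_quadratic_eigenvalues(axis):
    """I = c^2 along one physical axis has Hessian eigenvalues (0, 0, 2):
    Gaussian smoothing preserves the second derivative of a quadratic."""
    shape = [10, 12, 14]
    shape[axis] = 40
    coords = np.arange(shape[axis]) * ANISO[axis]
    view = [None, None, None]
    view[axis] = slice(None)
    data = np.broadcast_to(coords[tuple(view)] ** 2, shape).copy()
    eig = hessian_eigenvalues(fc.ImageVolume(data, ANISO), BonenessParams())
    # stay clear of the boundary along the varying axis (kernel radius)
    inner = [slice(2, -2)] * 3
    inner[axis] = slice(8, -8)
    inner = tuple(inner)
    assert np.allclose(eig.lambda3[inner], 2.0, atol=1e-6)
    assert np.abs(eig.lambda1[inner]).max() < 1e-6
    assert np.abs(eig.lambda2[inner]).max() < 1e-6


def test_bright_sheet_dominant_negative_eigenvalue():
    """A bright Gaussian sheet normal to z: lambda3 < 0 and dominant at the
    sheet centre, matching the closed-form second derivative of the profile."""
    nz, w = 41, 2.0  # sheet sd, mm; 1 mm isotropic sampling resolves it
    iso = (1.0, 1.0, 1.0)
    z = (np.arange(nz) - nz // 2) * iso[0]
    profile = 1000.0 * np.exp(-(z ** 2) / (2 * w ** 2))
    data = np.broadcast_to(profile[:, None, None], (nz, 12, 12)).copy()
    scale = 1.0
    eig = hessian_eigenvalues(fc.ImageVolume(data, iso),
                              BonenessParams(hessian_scale=scale))
    centre = (nz // 2, 6, 6)
    # analytic: smoothed profile is a Gaussian with sd sqrt(w^2 + scale^2)
    s2 = w ** 2 + scale ** 2
    amp = 1000.0 * w / np.sqrt(s2)
    expected = -amp / s2  # f''(0) of amp*exp(-z^2/2 s2)
    l3 = eig.lambda3[centre]
    assert l3 < 0
    assert abs(eig.lambda1[centre]) < 0.05 * abs(l3)
    assert abs(eig.lambda2[centre]) < 0.05 * abs(l3)
    assert l3 == pytest.approx(expected, rel=0.05)


def test_regularizer_conventions():
    eig = fc.EigenField(
        lambda1=np.full((2, 2, 2), 1.0),
        lambda2=np.full((2, 2, 2), -2.0),
        lambda3=np.full((2, 2, 2), 3.0),
        spacing=(1, 1, 1), origin=(0, 0, 0),
    )
    assert regularizer_t(eig) == pytest.approx(6.0)
    assert regularizer_t(eig, convention="individual") == pytest.approx(2.0)
    roi = fc.BinaryMask(np.ones((2, 2, 2), bool), (1, 1, 1))
    assert regularizer_t(eig, roi) == pytest.approx(6.0)


def test_bje_formula_reference_value():
    """Eigen triple (0, 0, -10) with T = 10: R_bones = 0, R_noise = 1, so
    BJE = +1 * 1 * (1 - e^-4)."""
    val = bje_from_eigenvalues(0.0, 0.0, -10.0, 10.0)
    assert float(val) == pytest.approx(1.0 - np.exp(-4.0), abs=1e-12)
    # sign(0) = 0: flat voxel maps to exactly 0
    assert float(bje_from_eigenvalues(0.0, 0.0, 0.0, 10.0)) == 0.0


def test_constant_volume_warns_and_zero_map():
    vol = fc.ImageVolume(np.full((6, 6, 6), 50.0), ANISO)
    with pytest.warns(RuntimeWarning, match="constant input"):
        out = bje_map(vol)
    assert np.all(out.data == 0.0)


def test_range_and_sign_rule(rng):
    """|BJE| <= 1 everywhere and sign(BJE) = -sign(lambda3) voxel-wise."""
    vol = fc.ImageVolume(rng.uniform(-1000, 2000, (16, 16, 16)), ANISO)
    params = BonenessParams()
    eig = hessian_eigenvalues(vol, params)
    out = bje_map(vol, params)
    assert np.abs(out.data).max() <= 1.0
    sgn = np.sign(out.data)
    expect = -np.sign(eig.lambda3)
    assert ((sgn == expect) | (out.data == 0.0)).all()


def test_intensity_shift_and_scale_invariance(rng):
    """The map ignores constant offsets (Hessian kills them) and positive
    rescaling (both ratios are homogeneous of degree zero)."""
    data = rng.normal(0, 300, (14, 14, 14))
    base = bje_map(fc.ImageVolume(data, ANISO)).data
    shifted = bje_map(fc.ImageVolume(data + 777.0, ANISO)).data
    scaled = bje_map(fc.ImageVolume(data * 3.7, ANISO)).data
    assert np.allclose(base, shifted, atol=1e-9)
    assert np.allclose(base, scaled, atol=1e-9)


def test_phantom_map_polarity(small_phantom_clean):
    """Cortical shell maps near +1; the joint gap shows negative response,
    separating femur from pelvis in the boneness domain."""
    from scipy import ndimage

    ph = small_phantom_clean
    roi = fc.segment_body(ph.volume).mask
    out = bje_map(ph.volume, BonenessParams(roi=roi))
    femur = ph.femur_truth.data
    shell = femur & ~ndimage.binary_erosion(femur, iterations=2)
    gap = (ndimage.binary_dilation(femur, iterations=2)
           & ndimage.binary_dilation(ph.other_bone_truth.data, iterations=2)
           & ~femur & ~ph.other_bone_truth.data)
    assert gap.any()
    assert np.median(out.data[shell]) > 0.5
    assert np.median(out.data[gap]) < 0.0


def test_invalid_params():
    with pytest.raises(ValueError, match="hessian_scale"):
        BonenessParams(hessian_scale=0.0)
    with pytest.raises(ValueError, match="t_convention"):
        BonenessParams(t_convention="median")
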