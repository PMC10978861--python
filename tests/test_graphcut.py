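import itertools

import numpy as np
import pytest

import femurcut as fc
from femurcut.graphcut import (
    GraphCutParams,
    boundary_term,
    build_terms,
    energy,
    mincut_segment,
    regional_terms,
)

UNIT = (1.0, 1.0, 1.0)


def _vol(data, spacing=UNIT):
    return fc.ImageVolume(np.asarray(data, float), spacing)


def _seeds(labels, spacing=UNIT):
    return fc.SeedVolume(np.asarray(labels, np.uint8), spacing)


def _enumerate_minimum(vol, seeds, params):
    terms = build_terms(vol, seeds, params)
    n = vol.data.size
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n):
        lab = fc.BinaryMask(np.array(bits, bool).reshape(vol.shape), vol.spacing)
        best = min(best, energy(lab, terms, params))
    return best


class TestBoundaryTerm:
    def test_equal_values_hit_otherwise_branch(self):
        p = GraphCutParams()
        assert boundary_term(0.3, 0.3, p) == p.lam
        assert boundary_term(-0.2, 0.6, p) == p.lam

    def test_descending_reference_value(self):
        """BJE 1 -> 0 at sigma 0.25, lambda 100 in the exponent:
        exp(-100 / (2 * 0.0625)) = exp(-800)."""
        p = GraphCutParams(sigma=0.25, lam=100.0, lambda_in_exponent=True)
        assert boundary_term(1.0, 0.0, p) == pytest.approx(np.exp(-800.0))
        p2 = GraphCutParams(sigma=0.25, lam=100.0, lambda_in_exponent=False)
        assert boundary_term(1.0, 0.0, p2) == pytest.approx(np.exp(-8.0))

    def test_large_sigma_limit(self):
        p = GraphCutParams(sigma=1e9)
        assert boundary_term(0.5, 0.4, p) == pytest.approx(1.0)


class TestRegionalTerms:
    def test_seed_classes(self):
        lam = 100.0
        labels = np.zeros((1, 1, 3), np.uint8)
        labels[0, 0, 1] = 1  # foreground
        labels[0, 0, 2] = 2  # background
        t = regional_terms(_seeds(labels), GraphCutParams(lam=lam))
        # unlabelled
        assert (t.r_f[0, 0, 0], t.r_b[0, 0, 0]) == (0.0, 1.0)
        # foreground seed
        assert (t.r_f[0, 0, 1], t.r_b[0, 0, 1]) == (lam, 0.0)
        # background seed
        assert (t.r_f[0, 0, 2], t.r_b[0, 0, 2]) == (1.0, lam)


class TestEnergy:
    def test_uniform_labeling_cuts_nothing(self, rng):
        vol = _vol(rng.uniform(-1, 1, (2, 3, 3)))
        seeds = _seeds(np.zeros((2, 3, 3)))
        params = GraphCutParams()
        terms = build_terms(vol, seeds, params)
        allbg = fc.BinaryMask(np.zeros(vol.shape, bool), UNIT)
        assert energy(allbg, terms, params) == 0.0  # unlabelled bg costs r_f = 0
        allfg = fc.BinaryMask(np.ones(vol.shape, bool), UNIT)
        assert energy(allfg, terms, params) == vol.data.size  # r_b = 1 each

    def test_two_voxel_hand_computation(self):
        params = GraphCutParams(sigma=0.5, lam=10.0)
        vol = _vol([[[0.8, 0.2]]])
        seeds = _seeds([[[1, 2]]])
        terms = build_terms(vol, seeds, params)
        w = params.lam
        b_pq = np.exp(-10.0 * 0.36 / 0.5)  # descending 0.8 -> 0.2
        b_qp = 10.0                        # ascending branch
        cases = {
            (0, 0): 10.0 + 1.0,            # fg seed mislabelled + bg seed ok
            (1, 1): 0.0 + 10.0,            # both fg: bg seed pays lam
            (1, 0): 0.0 + 1.0 + w * b_pq,  # the intended cut
            (0, 1): 10.0 + 10.0 + w * b_qp,
        }
        for (a, b), expect in cases.items():
            lab = fc.BinaryMask(np.array([[[a, b]]], bool), UNIT)
            assert energy(lab, terms, params) == pytest.approx(expect), (a, b)


@pytest.mark.parametrize("solver", ["networkx", "scipy"])
def test_mincut_matches_exhaustive_minimum(solver, rng):
    """On random 3x3x1 instances the cut energy equals the brute-force
    minimum over all 512 labelings, for both flow backends."""
    params = GraphCutParams(solver=solver, keep_largest_component=False)
    for _ in range(25):
        vol = _vol(rng.uniform(-1, 1, (1, 3, 3)))
        labels = np.zeros((1, 3, 3), np.uint8)
        for _ in range(int(rng.integers(0, 4))):
            labels[0, rng.integers(0, 3), rng.integers(0, 3)] = rng.integers(1, 3)
        seeds = _seeds(labels)
        mask = mincut_segment(vol, seeds, params=params)
        got = energy(mask, build_terms(vol, seeds, params), params)
        want = _enumerate_minimum(vol, seeds, params)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-6)


def test_mincut_optimal_under_dialect_flags(rng):
    """The exactness of the minimization is independent of the dialect."""
    for le, lE, cap in [(False, True, True), (True, False, True), (True, True, False)]:
        params = GraphCutParams(lambda_in_exponent=le, lambda_in_energy=lE,
                                regional_as_capacity=cap,
                                keep_largest_component=False)
        vol = _vol(rng.uniform(-1, 1, (1, 3, 3)))
        labels = np.zeros((1, 3, 3), np.uint8)
        labels[0, 0, 0], labels[0, 2, 2] = 1, 2
        seeds = _seeds(labels)
        mask = mincut_segment(vol, seeds, params=params)
        got = energy(mask, build_terms(vol, seeds, params), params)
        assert got == pytest.approx(_enumerate_minimum(vol, seeds, params),
                                    rel=1e-9, abs=1e-6)


def test_all_foreground_seeding_gives_all_foreground(rng):
    vol = _vol(rng.uniform(-1, 1, (2, 4, 4)))
    seeds = _seeds(np.ones((2, 4, 4)))
    mask = mincut_segment(vol, seeds)
    assert mask.data.all()


def test_no_seeds_uniform_map_all_background():
    vol = _vol(np.zeros((2, 4, 4)))
    seeds = _seeds(np.zeros((2, 4, 4)))
    with pytest.warns(RuntimeWarning, match="empty segmentation"):
        mask = mincut_segment(vol, seeds)
    assert not mask.data.any()


def test_roi_forces_background(rng):
    """Outside the ROI nothing is ever foreground; inside, an all-seeded
    problem fills the ROI (the boundary faces crossing out of the ROI do
    not belong to the optimized subgraph)."""
    vol = _vol(rng.uniform(-1, 1, (2, 4, 4)))
    labels = np.ones((2, 4, 4), np.uint8)
    roi = np.zeros((2, 4, 4), bool)
    roi[:, :2, :] = True
    mask = mincut_segment(vol, _seeds(labels),
                          roi=fc.BinaryMask(roi, UNIT),
                          params=GraphCutParams(keep_largest_component=False))
    assert not mask.data[~roi].any()
    assert mask.data[roi].all()


def test_seed_compliance_on_phantom(small_phantom):
    """With the default lambda every seeded voxel keeps its label."""
    ph = small_phantom
    roi = fc.segment_body(ph.volume).mask
    bje = fc.bje_map(ph.volume, fc.BonenessParams(roi=roi))
    seeds = fc.synth_seeds(ph.femur_truth, n_slices=3, rng_seed=5,
                           within=ph.body_truth)
    mask = mincut_segment(bje, seeds, roi=roi)
    assert mask.data[seeds.foreground].all()
    assert not mask.data[seeds.background].any()


def test_determinism(small_phantom):
    ph = small_phantom
    roi = fc.segment_body(ph.volume).mask
    bje = fc.bje_map(ph.volume, fc.BonenessParams(roi=roi))
    seeds = fc.synth_seeds(ph.femur_truth, n_slices=3, rng_seed=5,
                           within=ph.body_truth)
    a = mincut_segment(bje, seeds, roi=roi)
    b = mincut_segment(bje, seeds, roi=roi)
    assert np.array_equal(a.data, b.data)


def test_param_validation():
    with pytest.raises(ValueError, match="sigma"):
        GraphCutParams(sigma=0.0)
    with pytest.raises(ValueError, match="connectivity"):
        GraphCutParams(connectivity=10)
    with pytest.raises(ValueError, match="solver"):
        GraphCutParams(solver="gpu")
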