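"""3D soma detection, counting, pool extents, and projections."""

import numpy as np
import pytest

from meptrace.neurons import (
    PoolExtent,
    SpotParams,
    SpotSet,
    count_neurons,
    detect_spots,
    max_intensity_projection,
    pool_extent,
)


def _blob_volume(centres_um, shape=(40, 40, 40), vox=5.0, peak=100.0,
                 diameter=20.0, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    vol = rng.normal(10.0, noise_sd, size=shape) if noise_sd else \
        np.full(shape, 10.0)
    sigma = diameter / 4.0 / vox
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    for c in centres_um:
        cv = np.asarray(c) / vox - 0.5
        r2 = sum(((g - cc) / sigma) ** 2 for g, cc in zip(grids, cv))
        vol += peak * np.exp(-0.5 * r2)
    return np.clip(vol, 0, None)


def test_single_soma_detected_at_truth_position():
    truth = np.array([[102.0, 97.0, 100.0]])
    vol = _blob_volume(truth, noise_sd=10.0, peak=100.0, seed=1)  # SNR 10
    spots = detect_spots(vol, (5.0, 5.0, 5.0), SpotParams())
    assert count_neurons(spots) == 1
    assert np.linalg.norm(spots.centroids_um[0] - truth[0]) <= 5.0  # 1 voxel


def test_well_separated_somata_both_found():
    truth = np.array([[50.0, 50.0, 50.0], [110.0, 50.0, 50.0]])  # 3x diameter
    vol = _blob_volume(truth, noise_sd=5.0, seed=2)
    spots = detect_spots(vol, (5.0, 5.0, 5.0), SpotParams())
    assert count_neurons(spots) == 2


def test_pure_background_yields_no_spots():
    vol = _blob_volume([], noise_sd=8.0, seed=3)
    spots = detect_spots(vol, (5.0, 5.0, 5.0),
                         SpotParams(intensity_threshold=200.0))
    assert count_neurons(spots) == 0
    assert len(spots.centroids_um) == 0


def test_detection_is_deterministic():
    truth = np.array([[60.0, 80.0, 100.0], [140.0, 80.0, 100.0]])
    vol = _blob_volume(truth, noise_sd=10.0, seed=4)
    a = detect_spots(vol, (5.0, 5.0, 5.0))
    b = detect_spots(vol, (5.0, 5.0, 5.0))
    np.testing.assert_array_equal(a.centroids_um, b.centroids_um)
    np.testing.assert_array_equal(a.intensities, b.intensities)


def test_anisotropic_voxel_validation():
    vol = np.zeros((10, 10, 10))
    with pytest.raises(ValueError, match="2 voxels"):
        detect_spots(vol, (15.0, 5.0, 5.0), SpotParams(expected_diameter_um=20))
    with pytest.raises(ValueError, match="3D"):
        detect_spots(np.zeros((5, 5)), (5.0, 5.0, 5.0))


# ------------------------------------------------------------ extents

def _spotset(centroids):
    c = np.asarray(centroids, dtype=float)
    return SpotSet(centroids_um=c, intensities=np.ones(len(c)))


def test_two_point_extent():
    ext = pool_extent(_spotset([[0, 0, 0], [100, 20, 10]]))
    assert ext.as_tuple() == (100.0, 20.0, 10.0)


def test_single_spot_extent_is_zero():
    assert pool_extent(_spotset([[5, 5, 5]])).as_tuple() == (0.0, 0.0, 0.0)


def test_extent_order_statistics_uniform():
    rng = np.random.default_rng(7)
    L = 1000.0
    pts = rng.uniform(0, L, size=(1000, 3))
    mm = pool_extent(_spotset(pts), mode="minmax")
    pc = pool_extent(_spotset(pts), mode="percentile")
    for axis in range(3):
        assert mm.as_tuple()[axis] == pytest.approx(L, rel=0.02)
        assert pc.as_tuple()[axis] < mm.as_tuple()[axis]


def test_extent_translation_invariance_and_scaling():
    rng = np.random.default_rng(8)
    pts = rng.uniform(0, 100, size=(50, 3))
    base = np.array(pool_extent(_spotset(pts)).as_tuple())
    shifted = np.array(pool_extent(_spotset(pts + 123.4)).as_tuple())
    scaled = np.array(pool_extent(_spotset(pts * 2.5)).as_tuple())
    np.testing.assert_allclose(shifted, base, atol=1e-9)
    np.testing.assert_allclose(scaled, 2.5 * base, rtol=1e-9)


def test_extent_errors():
    with pytest.raises(ValueError, match="empty"):
        pool_extent(SpotSet(np.empty((0, 3)), np.empty(0)))
    with pytest.raises(ValueError, match="mode"):
        pool_extent(_spotset([[0, 0, 0]]), mode="iqr")


# ---------------------------------------------------------------- MIP

def test_mip_single_bright_voxel_and_constant():
    vol = np.zeros((4, 5, 6))
    vol[2, 3, 4] = 7.0
    mip = max_intensity_projection(vol, axis=0)
    assert mip[3, 4] == 7.0 and mip.sum() == 7.0
    assert np.all(max_intensity_projection(np.full((3, 3, 3), 2.0)) == 2.0)


def test_mip_commutes_with_monotone_rescaling():
    rng = np.random.default_rng(9)
    vol = rng.random((6, 7, 8))
    for axis in range(3):
        mip = max_intensity_projection(vol, axis)
        rescaled = max_intensity_projection(3.0 * vol + 1.0, axis)
        np.testing.assert_allclose(rescaled, 3.0 * mip + 1.0)


def test_mip_axis_out_of_bounds():
    with pytest.raises(ValueError, match="axis"):
        max_intensity_projection(np.zeros((2, 2, 2)), axis=3)
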