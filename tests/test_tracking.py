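import numpy as np
import pytest

from tracerval.phantom import GM, WM
from tracerval.tensors import TensorField
from tracerval.tracking import (
    SeedRegion,
    TrackingParams,
    build_seed_region,
    fact_track,
    probabilistic_track,
    select_streamlines,
    whole_brain_seeds,
)


H = 0.3


def uniform_field(shape=(20, 10, 10), axis=0, fa_low_mask=None):
    lam = [2e-4, 2e-4, 2e-4]
    lam[axis] = 1.7e-3
    tensors = np.zeros(shape + (3, 3)) + np.diag(lam)
    if fa_low_mask is not None:
        tensors[fa_low_mask] = 7e-4 * np.eye(3)
    return TensorField.from_tensors(tensors, voxel_size=(H, H, H))


def test_seed_region_dw0_is_injection_exactly(small_fitted):
    cfg, tissue, tf, interface = small_fitted
    sr = build_seed_region(tissue.injection_mask, interface, tissue.label_volume == WM, 0.0)
    inj = np.argwhere(tissue.injection_mask)
    assert np.array_equal(np.sort(sr.voxels, axis=0), np.sort(inj, axis=0))


def test_seed_region_slab_extension_adds_expected_layers(small_fitted):
    """On the flat slab (0.3 mm voxels): d_w = 0.3 adds exactly the one WM
    layer beneath each injection interface voxel, d_w = 0.6 adds two."""
    cfg, tissue, tf, interface = small_fitted
    wm = tissue.label_volume == WM
    inj_cols = tissue.injection_mask[:, :, cfg.gm_start]
    n_cols = int(inj_cols.sum())
    sr0 = build_seed_region(tissue.injection_mask, interface, wm, 0.0, cfg.voxel_size)
    sr1 = build_seed_region(tissue.injection_mask, interface, wm, 0.3, cfg.voxel_size)
    sr2 = build_seed_region(tissue.injection_mask, interface, wm, 0.6, cfg.voxel_size)
    added1 = len(sr1) - len(sr0)
    assert added1 == n_cols
    ext1 = sr1.voxels[wm[tuple(sr1.voxels.T)]]
    assert np.all(ext1[:, 2] == cfg.gm_start - 1)
    # d_w = 0.6: the second layer directly beneath each column, plus the
    # first-layer ring within 0.6 mm (Euclidean) of an edge interface voxel
    ext2 = sr2.voxels[wm[tuple(sr2.voxels.T)]]
    layers = np.unique(ext2[:, 2])
    assert set(layers) == {cfg.gm_start - 2, cfg.gm_start - 1}
    deep = ext2[ext2[:, 2] == cfg.gm_start - 2]
    assert len(deep) == n_cols
    assert np.array_equal(np.sort(deep[:, :2], axis=0), np.sort(np.argwhere(inj_cols), axis=0))
    # monotone nesting
    as_set = lambda s: set(map(tuple, s.voxels))
    assert as_set(sr0) <= as_set(sr1) <= as_set(sr2)


def test_seed_region_negative_depth_rejected(small_fitted):
    cfg, tissue, tf, interface = small_fitted
    with pytest.raises(ValueError, match="d_w"):
        build_seed_region(tissue.injection_mask, interface, tissue.label_volume == WM, -0.1)


def test_fact_straight_lines_in_uniform_field():
    tf = uniform_field()
    params = TrackingParams()
    ss = fact_track(tf, whole_brain_seeds(tf, params), params)
    assert len(ss) == 20 * 10 * 10
    for s, seed in zip(ss.streamlines, ss.seed_voxels):
        assert len(s) >= 2
        centre = (seed[1:] + 0.5) * H
        assert np.abs(s[:, 1:] - centre).max() < 0.5 * H  # no perpendicular drift
        assert s[:, 0].max() - s[:, 0].min() > 18 * H  # spans the volume


def test_fact_low_fa_seed_not_seeded():
    low = np.zeros((20, 10, 10), dtype=bool)
    low[5, 5, 5] = True
    tf = uniform_field(fa_low_mask=low)  # isotropic voxel, FA ~ 0 < start 0.1
    params = TrackingParams()
    ss = fact_track(tf, whole_brain_seeds(tf, params), params)
    assert not any((s == [5, 5, 5]).all() for s in ss.seed_voxels)


def test_fact_stop_fa_terminates_inside_voxel():
    low = np.zeros((20, 1, 1), dtype=bool)
    low[10:] = True
    tf = uniform_field(shape=(20, 1, 1), fa_low_mask=low)
    params = TrackingParams()
    ss = fact_track(tf, SeedRegion(voxels=np.array([[2, 0, 0]])), params)
    s = ss.streamlines[0]
    # last vertex is the centre of the first low-FA voxel (x index 10)
    assert s[:, 0].max() == pytest.approx((10 + 0.5) * H)
    vis = np.unravel_index(ss.visited[0], (20, 1, 1))[0]
    assert 10 in vis and 11 not in vis


def test_fact_determinism(small_fitted):
    cfg, tissue, tf, interface = small_fitted
    params = TrackingParams()
    seeds = whole_brain_seeds(tf, params)
    a = fact_track(tf, seeds, params)
    b = fact_track(tf, seeds, params)
    assert len(a) == len(b)
    assert all(np.array_equal(x, y) for x, y in zip(a.streamlines, b.streamlines))


def test_fact_vertex_spacing_and_bounds(small_fitted):
    cfg, tissue, tf, interface = small_fitted
    params = TrackingParams()
    ss = fact_track(tf, whole_brain_seeds(tf, params), params)
    extent = np.asarray(cfg.grid_shape) * np.asarray(cfg.voxel_size)
    rng = np.random.default_rng(0)
    for i in rng.integers(0, len(ss), size=50):
        s = ss.streamlines[i]
        assert np.all(s >= -1e-9) and np.all(s <= extent + 1e-9)
        gaps = np.linalg.norm(np.diff(s, axis=0), axis=1)
        assert gaps.max() <= ss.step_length + 1e-9


def test_fact_empty_seed_warns():
    tf = uniform_field()
    with pytest.warns(UserWarning, match="empty"):
        ss = fact_track(tf, SeedRegion(voxels=np.empty((0, 3), int)), TrackingParams())
    assert len(ss) == 0


def test_select_streamlines_requires_both_regions():
    tf = uniform_field()
    params = TrackingParams()
    ss = fact_track(tf, SeedRegion(voxels=np.array([[10, 5, 5]])), params)
    vol_a = np.zeros((20, 10, 10), bool)
    vol_a[:, 5, 5] = True  # the streamline's own column
    vol_b = np.zeros((20, 10, 10), bool)
    vol_b[0, 5, 5] = True
    off = np.zeros((20, 10, 10), bool)
    off[0, 0, 0] = True
    assert len(select_streamlines(ss, vol_a, vol_b)) == 1
    assert len(select_streamlines(ss, vol_a, off)) == 0  # never visits region b
    with pytest.raises(ValueError, match="nonempty"):
        select_streamlines(ss, vol_a, np.zeros((20, 10, 10), bool))


# --- probabilistic tracker --------------------------------------------------


def _prob_setup(shape=(20, 6, 6)):
    tf = uniform_field(shape=shape)
    seed = SeedRegion(voxels=np.array([[1, 3, 3]]))
    way = np.zeros(shape, bool)
    way[1, :, :] = True  # seed plane: every sample passes the waypoint
    term = np.zeros(shape, bool)
    term[18, :, :] = True
    return tf, seed, way, term


def test_prob_sigma_zero_is_deterministic_straight_line():
    tf, seed, way, term = _prob_setup()
    params = TrackingParams(n_samples=16, distance_correction=False)
    dens, info = probabilistic_track(tf, seed, way, term, params,
                                     orientation_sigma=0.0, rng_seed=1)
    assert info["n_retained"] == 16
    support = np.argwhere(dens > 0)
    assert np.all(support[:, 1] == 3) and np.all(support[:, 2] == 3)  # one column
    assert support[:, 0].max() == 18  # forward-going samples reach the termination plane


def test_prob_unreachable_waypoint_discards_all():
    tf, seed, way, term = _prob_setup()
    way[:] = False
    way[10, 0, 0] = True  # off the only possible path
    params = TrackingParams(n_samples=8, distance_correction=False)
    with pytest.warns(UserWarning, match="retained no samples"):
        dens, info = probabilistic_track(tf, seed, way, term, params,
                                         orientation_sigma=0.0, rng_seed=1)
    assert dens.sum() == 0
    assert info["n_retained"] == 0


def test_prob_distance_correction_scales_by_mean_length():
    tf, seed, way, term = _prob_setup()
    kw = dict(orientation_sigma=0.05, rng_seed=3)
    p_off = TrackingParams(n_samples=64, distance_correction=False)
    p_on = TrackingParams(n_samples=64, distance_correction=True)
    d_off, info_off = probabilistic_track(tf, seed, way, term, p_off, **kw)
    d_on, info_on = probabilistic_track(tf, seed, way, term, p_on, **kw)
    mask = d_off > 0
    ratio = d_on[mask] / d_off[mask]
    assert np.allclose(ratio, info_on["mean_retained_length_mm"], rtol=0.05)


def test_prob_reproducible_given_seed():
    tf, seed, way, term = _prob_setup()
    params = TrackingParams(n_samples=32)
    a, _ = probabilistic_track(tf, seed, way, term, params, orientation_sigma=0.2, rng_seed=5)
    b, _ = probabilistic_track(tf, seed, way, term, params, orientation_sigma=0.2, rng_seed=5)
    assert np.array_equal(a, b)


def test_prob_invalid_inputs():
    tf, seed, way, term = _prob_setup()
    with pytest.raises(ValueError, match="n_samples"):
        probabilistic_track(tf, seed, way, term, TrackingParams(n_samples=0))
    with pytest.raises(ValueError, match="orientation_sigma"):
        probabilistic_track(tf, seed, way, term, TrackingParams(n_samples=4),
                            orientation_sigma=-0.1)


def test_tracking_params_validation():
    with pytest.raises(ValueError):
        TrackingParams(start_fa=1.5)
    with pytest.raises(ValueError):
        TrackingParams(stop_angle=0.0)
    with pytest.raises(ValueError):
        TrackingParams(curvature_threshold=2.0)
    defaults = TrackingParams()
    assert (defaults.start_fa, defaults.stop_fa, defaults.stop_angle) == (0.1, 0.2, 70.0)
    assert (defaults.n_samples, defaults.curvature_threshold, defaults.step_length) == (10000, 0.2, 0.1)
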