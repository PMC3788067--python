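import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tracerval.histology import (
    FiberFilters,
    Micrograph,
    boundary_shift_robustness,
    count_somas,
    extract_crossing_fibers,
    fit_boundary_curve,
    grid_counts,
    segment_fiber_objects,
    tophat_correct,
)


def _micro(img):
    return Micrograph(image=np.asarray(img, dtype=float), resolution=0.87)


def test_tophat_of_flat_image_is_zero():
    out = tophat_correct(_micro(np.full((64, 64), 0.5)), element_radius=5)
    assert np.abs(out.image).max() < 1e-12


def test_tophat_removes_illumination_ramp():
    """Fiber contrast after correction is within 10% of the ramp-free case."""
    base = np.full((128, 128), 0.8)
    base[60:64, 20:100] = 0.3  # dark bar
    ramp = base + 0.3 * np.linspace(-0.5, 0.5, 128)[None, :]
    c0 = tophat_correct(_micro(base), 8, presmooth_sigma=0).image
    c1 = tophat_correct(_micro(ramp), 8, presmooth_sigma=0).image
    peak0 = c0[62, 20:100].mean()
    peak1 = c1[62, 20:100].mean()
    assert abs(peak1 - peak0) / peak0 < 0.10


def test_tophat_near_idempotent():
    rng = np.random.default_rng(0)
    img = 0.7 + 0.1 * np.sin(np.linspace(0, 3, 96))[None, :] * np.ones((96, 1))
    img[40:43, 10:80] -= 0.4
    once = tophat_correct(_micro(img), 8, presmooth_sigma=0).image
    twice = tophat_correct(_micro(-once + once.max()), 8, presmooth_sigma=0).image
    # energy change under re-application stays within 5%
    assert abs(twice.sum() - once.sum()) / once.sum() < 0.05


def test_tophat_element_larger_than_image_rejected():
    with pytest.raises(ValueError, match="larger"):
        tophat_correct(_micro(np.zeros((20, 20))), element_radius=15)


def _planted_scene():
    """5 elongated fibers and 3 round blobs on a bright background."""
    img = np.full((256, 256), 0.8)
    for k in range(5):
        r = 30 + 40 * k
        img[r : r + 3, 40:140] = 0.2
    yy, xx = np.mgrid[0:256, 0:256]
    for cx, cy in [(200, 40), (200, 120), (200, 200)]:
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= 81] = 0.2
    return img


def test_shape_filters_remove_round_blobs():
    corrected = tophat_correct(_micro(_planted_scene()), 10, presmooth_sigma=0)
    objs = segment_fiber_objects(corrected)
    assert len(objs) == 5
    assert (objs.table["elongation"] >= 20).all()


def test_empty_image_yields_no_objects():
    objs = segment_fiber_objects(_micro(np.zeros((64, 64))))
    assert len(objs) == 0


def test_lowering_area_min_admits_more_objects():
    corrected = tophat_correct(_micro(_planted_scene()), 10, presmooth_sigma=0)
    strict = segment_fiber_objects(corrected, filters=FiberFilters(area_min=20, elongation_min=1e-6))
    loose = segment_fiber_objects(corrected, filters=FiberFilters(area_min=1, elongation_min=1e-6))
    assert len(loose) >= len(strict)
    assert len(strict) == 8  # all planted objects pass without the shape filter


def test_segmentation_invariant_to_constant_offset():
    scene = _planted_scene()
    a = segment_fiber_objects(tophat_correct(_micro(scene), 10, presmooth_sigma=0))
    b = segment_fiber_objects(tophat_correct(_micro(scene + 0.1), 10, presmooth_sigma=0))
    assert len(a) == len(b)
    assert np.allclose(np.sort(a.table["area"]), np.sort(b.table["area"]))


# --- boundary curve ---------------------------------------------------------


def test_collinear_markers_give_straight_band():
    markers = np.column_stack([np.linspace(5, 120, 8), np.full(8, 40.0)])
    curve = fit_boundary_curve(markers, width=6)
    band = curve.band_mask((80, 128))
    cols = band[:, 10:118]
    thickness = cols.sum(axis=0)
    assert np.all(np.abs(thickness - 6) <= 1)
    rows = np.where(band.any(axis=1))[0]
    assert rows.min() >= 36 and rows.max() <= 44


def test_circle_markers_fit_within_one_pixel():
    theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    markers = np.column_stack([64 + 40 * np.cos(theta), 64 + 40 * np.sin(theta)])
    markers = np.vstack([markers, markers[:1]])  # close the loop
    curve = fit_boundary_curve(markers, width=3)
    r = np.linalg.norm(curve.polyline - [64, 64], axis=1)
    assert np.abs(r - 40).max() < 1.0


def test_duplicate_markers_deduplicated_with_warning():
    markers = np.array([[0, 0], [10, 3], [10, 3], [20, 1], [30, 4.0]])
    with pytest.warns(UserWarning, match="duplicate"):
        curve = fit_boundary_curve(markers, width=6)
    assert len(curve.markers) == 4


def test_too_few_markers_rejected():
    with pytest.raises(ValueError, match="4"):
        fit_boundary_curve(np.array([[0, 0], [5, 5], [9, 9.0]]), width=6)


def test_crossing_extraction_contract():
    corrected = tophat_correct(_micro(_planted_scene()), 10, presmooth_sigma=0)
    objs = segment_fiber_objects(corrected)
    # vertical boundary through the fibers at x = 90
    markers = np.column_stack([np.full(8, 90.0), np.linspace(5, 250, 8)])
    curve = fit_boundary_curve(markers, width=6)
    crossing = extract_crossing_fibers(objs, curve)
    assert len(crossing) == 5  # every bar straddles the band
    # centroids are full-object centroids, not intersection centroids
    assert np.allclose(np.sort(crossing[:, 0]), np.full(5, 89.5), atol=1.0)
    # a boundary far from everything selects nothing
    far = fit_boundary_curve(
        np.column_stack([np.full(8, 245.0), np.linspace(5, 250, 8)]), width=6
    )
    assert len(extract_crossing_fibers(objs, far)) == 0


def test_boundary_shift_zero_is_invariant_and_short_fibers_drop():
    corrected = tophat_correct(_micro(_planted_scene()), 10, presmooth_sigma=0)
    objs = segment_fiber_objects(corrected)
    markers = np.column_stack([np.full(8, 90.0), np.linspace(5, 250, 8)])
    curve = fit_boundary_curve(markers, width=6)
    lo, mid, hi = boundary_shift_robustness(objs, curve, 0)
    assert lo == mid == hi
    # the bars span x in [40, 140]; +-60 px leaves that footprint entirely
    lo, mid, hi = boundary_shift_robustness(objs, curve, 60)
    assert lo < mid and hi < mid


def test_boundary_shift_leaving_image_rejected():
    corrected = tophat_correct(_micro(_planted_scene()), 10, presmooth_sigma=0)
    objs = segment_fiber_objects(corrected)
    markers = np.column_stack([np.full(8, 90.0), np.linspace(5, 250, 8)])
    curve = fit_boundary_curve(markers, width=6)
    with pytest.raises(ValueError, match="leaves the image"):
        boundary_shift_robustness(objs, curve, 500)


# --- gridding ---------------------------------------------------------------


def test_grid_unit_size_matches_standard_micrograph():
    ddm = grid_counts(np.empty((0, 2)), 6660.0, (256, 256))
    assert ddm.unit_size == pytest.approx(6660.0 / 256)
    assert ddm.unit_size == pytest.approx(26.015625)


def test_single_centroid_lands_in_first_cell():
    ddm = grid_counts(np.array([[0.0, 0.0]]), 6660.0)
    assert ddm.counts[0, 0] == 1
    assert ddm.total() == 1


def test_far_edge_centroid_clamped_into_last_cell():
    ddm = grid_counts(np.array([[6660.0, 6660.0]]), 6660.0)
    assert ddm.counts[255, 255] == 1


def test_centroid_outside_image_listed():
    with pytest.raises(ValueError, match="outside"):
        grid_counts(np.array([[7000.0, 10.0]]), 6660.0)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_grid_counts_conserves_mass_and_ignores_order(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 6660, size=(rng.integers(1, 1000), 2))
    ddm = grid_counts(pts, 6660.0)
    assert ddm.total() == len(pts)
    shuffled = grid_counts(pts[rng.permutation(len(pts))], 6660.0)
    assert np.array_equal(ddm.counts, shuffled.counts)


def test_count_somas_shares_gridding():
    rng = np.random.default_rng(1)
    pts = rng.uniform(0, 6660, size=(250, 2))
    fibers = grid_counts(pts, 6660.0)
    somas = count_somas(pts, 6660.0)
    assert np.array_equal(fibers.counts, somas.counts)
    assert somas.provenance == "bda_soma"
    assert somas.total() == 250
    assert count_somas(np.empty((0, 2)), 6660.0).total() == 0
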