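import numpy as np
import pytest

from tracerval.deformation import DeformationField, make_deformation
from tracerval.histology import grid_counts
from tracerval.phantom import GM, WM
from tracerval.transfer import (
    extract_interface,
    plane_density_to_interface,
    project_to_interface,
    tps_fit,
    transfer_ddm,
)


# --- interface --------------------------------------------------------------


def test_interface_voxels_touch_both_tissues(small_phantom):
    cfg, tissue, _ = small_phantom
    interface = extract_interface(tissue.label_volume, cfg.voxel_size)
    labels = tissue.label_volume
    offs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    for v in interface.voxels[:: max(len(interface) // 50, 1)]:
        assert labels[tuple(v)] == GM
        nb = v + offs
        ok = np.all((nb >= 0) & (nb < labels.shape), axis=1)
        classes = {labels[tuple(p)] for p in nb[ok]}
        assert WM in classes
    # slab: outward normals point from white into gray matter (+z)
    assert np.allclose(interface.normals[:, 2], 1.0)


# --- thin-plate spline ------------------------------------------------------


def test_tps_reproduces_affine_maps():
    rng = np.random.default_rng(0)
    src = rng.uniform(0, 150, (25, 2))
    A = np.array([[1.3, 0.2], [-0.3, 0.8]])
    fld = tps_fit(src, src @ A.T + [4.0, -2.0], regularization=0.0)
    assert np.abs(fld.nonlinear_weights).max() < 1e-8
    pts = rng.uniform(0, 150, (40, 2))
    assert np.abs(fld.map_points(pts) - (pts @ A.T + [4.0, -2.0])).max() < 1e-6
    assert np.allclose(fld.jacobian_det_at(pts), np.linalg.det(A), atol=1e-8)


def test_tps_interpolates_landmarks_at_zero_regularization():
    rng = np.random.default_rng(1)
    src = rng.uniform(0, 200, (30, 2))
    dst = src + rng.normal(0, 10, src.shape)
    fld = tps_fit(src, dst, regularization=0.0)
    assert np.abs(fld.map_points(src) - dst).max() < 1e-6


def test_tps_collinear_landmarks_need_regularization():
    src = np.column_stack([np.arange(5.0), np.arange(5.0)])
    with pytest.raises(ValueError, match="landmark"):
        tps_fit(src, src + 1.0, regularization=0.0)


def test_tps_generalizes_to_held_out_points():
    """Prediction error at held-out points < 5% of the displacement scale."""
    fld_true = make_deformation((256, 256), 12.0, rng_seed=4)
    rng = np.random.default_rng(2)
    train = rng.uniform(20, 236, (50, 2))
    test = rng.uniform(40, 216, (30, 2))
    fld = tps_fit(train, fld_true.map_points(train), regularization=0.0)
    err = np.linalg.norm(fld.map_points(test) - fld_true.map_points(test), axis=1)
    disp = np.linalg.norm(fld_true.displacement_at(test), axis=1)
    rms = lambda v: float(np.sqrt(np.mean(v**2)))
    assert rms(err) < 0.05 * rms(disp)


def test_tps_landmark_count_mismatch():
    with pytest.raises(ValueError, match="landmark"):
        tps_fit(np.zeros((5, 2)), np.zeros((4, 2)))


# --- density transfer -------------------------------------------------------


def test_transfer_identity_is_exact():
    rng = np.random.default_rng(3)
    ddm = grid_counts(rng.uniform(0, 2560, (800, 2)), 2560.0)
    out = transfer_ddm(ddm, DeformationField.identity((256, 256)))
    assert np.abs(out.counts - ddm.counts).max() < 1e-12


def test_transfer_magnification_compensates_density():
    """2x magnification: per-cell density scales by 1/4, total mass is kept."""
    rng = np.random.default_rng(4)
    pts = rng.uniform(200, 1000, (4000, 2))
    ddm = grid_counts(pts, 2560.0)
    out = transfer_ddm(ddm, DeformationField.from_affine(2 * np.eye(2)))
    assert abs(out.total() - ddm.total()) < 1e-6 * ddm.total()
    # compare a magnified block against the source block mass (block edges
    # split cells under the bilinear pull-back, hence the 1% slack)
    src_block = ddm.counts[20:100, 20:100].sum()
    dst_block = out.counts[40:200, 40:200].sum()
    assert dst_block == pytest.approx(src_block, rel=0.01)
    nz = out.counts[out.counts > 0]
    assert np.median(nz) <= np.median(ddm.counts[ddm.counts > 0])


def test_transfer_conserves_mass_and_composes():
    rng = np.random.default_rng(5)
    pts = rng.uniform(400, 2100, (5000, 2))
    ddm = grid_counts(pts, 2560.0)
    f = make_deformation((2560, 2560), 50.0, rng_seed=6)
    g = make_deformation((2560, 2560), 40.0, rng_seed=7)
    once = transfer_ddm(transfer_ddm(ddm, f), g)
    assert abs(once.total() - ddm.total()) / ddm.total() < 0.01

    def composed_field():
        def disp(p):
            return g.map_points(f.map_points(p)) - p

        def jac(p):
            Jf = f.jacobian_fn(p)
            Jg = g.jacobian_fn(f.map_points(p))
            return np.einsum("nij,njk->nik", Jg, Jf)

        return DeformationField(ndim=2, shape=(2560, 2560), displacement_fn=disp, jacobian_fn=jac)

    direct = transfer_ddm(ddm, composed_field())
    a = once.counts.reshape(32, 8, 32, 8).sum(axis=(1, 3))
    b = direct.counts.reshape(32, 8, 32, 8).sum(axis=(1, 3))
    assert 0.5 * np.abs(a / a.sum() - b / b.sum()).sum() < 0.02


def test_transfer_agrees_with_particle_oracle():
    rng = np.random.default_rng(8)
    for k in range(3):
        pts = rng.uniform(400, 2100, (4000, 2))
        ddm = grid_counts(pts, 2560.0)
        fld = make_deformation((2560, 2560), 60.0, rng_seed=20 + k)
        out = transfer_ddm(ddm, fld)
        oracle = grid_counts(fld.map_points(pts), 2560.0)
        a = out.counts.reshape(16, 16, 16, 16).sum(axis=(1, 3))
        b = oracle.counts.reshape(16, 16, 16, 16).sum(axis=(1, 3))
        tv = 0.5 * np.abs(a / a.sum() - b / b.sum()).sum()
        assert tv < 0.02


def test_transfer_rejects_folding_field_in_support():
    ddm = grid_counts(np.random.default_rng(9).uniform(200, 2300, (500, 2)), 2560.0)
    folding = DeformationField.from_affine(np.diag([-1.0, 1.0]), offset=[2560.0, 0.0])
    with pytest.raises(ValueError, match="determinant"):
        transfer_ddm(ddm, folding)


# --- interface projection ---------------------------------------------------


def test_projection_conserves_mass_exactly(small_phantom):
    cfg, tissue, _ = small_phantom
    interface = extract_interface(tissue.label_volume, cfg.voxel_size)
    rng = np.random.default_rng(10)
    dens = np.where(tissue.label_volume == GM, rng.uniform(0, 2, tissue.label_volume.shape), 0.0)
    out = project_to_interface(dens, interface)
    assert out.total() == pytest.approx(dens.sum(), abs=1e-9)


def test_projection_single_voxel_and_column(small_phantom):
    cfg, tissue, _ = small_phantom
    interface = extract_interface(tissue.label_volume, cfg.voxel_size)
    imap = interface.index_map()
    dens = np.zeros(tissue.label_volume.shape)
    # a full GM column above one interface voxel lands on that voxel
    i, j = 7, 9
    dens[i, j, cfg.gm_start : cfg.gm_start + cfg.gm_thickness] = 1.0
    out = project_to_interface(dens, interface)
    target = imap[i, j, cfg.gm_start]
    assert out.density[target] == pytest.approx(cfg.gm_thickness)
    assert out.total() == pytest.approx(cfg.gm_thickness)


def test_projection_empty_interface_rejected(small_phantom):
    cfg, tissue, _ = small_phantom
    interface = extract_interface(tissue.label_volume, cfg.voxel_size)
    empty = type(interface)(voxels=np.empty((0, 3), int), shape=interface.shape,
                            voxel_size=interface.voxel_size)
    with pytest.raises(ValueError, match="empty"):
        project_to_interface(np.zeros(interface.shape), empty)


def test_plane_density_assignment_preserves_roi_totals(small_phantom):
    """Gridding ground-truth centroids and assigning cells to interface
    columns reproduces the per-region axon counts exactly (no deformation)."""
    from tracerval.phantom import make_ground_truth_fibers
    from tracerval.stats import regional_counts

    cfg, tissue, _ = small_phantom
    interface = extract_interface(tissue.label_volume, cfg.voxel_size)
    fibers, _ = make_ground_truth_fibers(tissue, rng_seed=6)
    pts = np.vstack([v for v in fibers.values() if len(v)])
    px_per_mm = 1000.0 / 7.5
    size_px = cfg.extent_mm[0] * px_per_mm
    ddm = grid_counts(pts, size_px)
    sddm = plane_density_to_interface(ddm, interface, px_per_mm)
    roi_ids = tissue.roi_label_map[tuple(interface.voxels.T)]
    totals = regional_counts(sddm, roi_ids)
    for roi, t in tissue.bundle_truth.items():
        assert totals.get(roi, 0.0) == pytest.approx(t["axon_count"])
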