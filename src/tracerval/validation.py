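"""Self-contained validation experiments.

Each function runs one property-based check of the pipeline from scratch and
returns the measured quantities as a dict of plain floats.  The checks mirror
the package's design guarantees: exact tensor round-trips on noiseless data,
FACT geometry on analytically known fields, mass conservation through the
DDM chain, thin-plate-spline reproduction properties, planted-truth
micrograph counting, definitional statistics oracles, and the end-to-end
recovery of ground-truth connectivity on the phantom.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .deformation import DeformationField, make_deformation
from .dwi import make_scheme, simulate_dwi
from .histology import (
    extract_crossing_fibers,
    fit_boundary_curve,
    grid_counts,
    segment_fiber_objects,
    tophat_correct,
)
from .micrograph_sim import make_micrograph
from .phantom import GM, WM, CrossingSpec, PhantomConfig, make_phantom
from .pipeline import RunConfig, _selection_band, run_experiment
from .stats import correlate, fit_proportional, topk_spearman, voxelwise_pearson
from .tensors import TensorField, fa_from_eigenvalues, fit_tensor
from .tracking import (
    TrackingParams,
    build_seed_region,
    fact_track,
    select_streamlines,
    whole_brain_seeds,
    SeedRegion,
)
from .tract_ddm import streamline_interface_ddm
from .transfer import extract_interface, project_to_interface, tps_fit, transfer_ddm
from .stats import regional_counts


def _seed(root: int, salt: str) -> int:
    h = hashlib.sha256(f"{root}:{salt}".encode()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


# ---------------------------------------------------------------------------
def tensor_roundtrip(seed: int = 0, n: int = 100) -> dict:
    """Noiseless simulate-and-refit of random positive-definite tensors."""
    rng = np.random.default_rng(_seed(seed, "tensor"))
    A = rng.normal(size=(n, 1, 1, 3, 3)) * 6e-4
    D = np.einsum("...ij,...kj->...ik", A, A) + 1e-4 * np.eye(3)
    scheme = make_scheme()  # 31 directions at b = 1200 plus one b0
    dwi = simulate_dwi(D, scheme, s0=1000.0, noise_sigma=0.0)
    tf = fit_tensor(dwi)
    err = np.linalg.norm(tf.tensor - D, axis=(-2, -1)) / np.linalg.norm(D, axis=(-2, -1))
    iso = np.full((1, 1, 1, 3, 3), 0.0)
    iso[..., 0, 0] = iso[..., 1, 1] = iso[..., 2, 2] = 7e-4
    tf_iso = fit_tensor(simulate_dwi(iso, scheme, s0=1000.0, noise_sigma=0.0))
    return {
        "max_rel_frobenius_error": float(err.max()),
        "fa_equal_eigenvalues": float(fa_from_eigenvalues(np.array([7e-4, 7e-4, 7e-4]))),
        "fa_refit_isotropic": float(tf_iso.fa.max()),
        "n": n,
    }


def fact_geometry(seed: int = 0) -> dict:
    """Straight-line propagation and 90-degree crossing-slab blocking."""
    shape = (40, 20, 20)
    h = 0.3
    tensors = np.zeros(shape + (3, 3))
    tensors[...] = np.diag([1.7e-3, 2e-4, 2e-4])  # principal axis x
    tf = TensorField.from_tensors(tensors, voxel_size=(h, h, h))
    params = TrackingParams()
    ss = fact_track(tf, whole_brain_seeds(tf, params), params)
    dev = 0.0
    for s, seed_vox in zip(ss.streamlines, ss.seed_voxels):
        centre_yz = (seed_vox[1:] + 0.5) * h
        dev = max(dev, float(np.abs(s[:, 1:] - centre_yz).max()))
    # crossing slab: x-aligned field with a y-aligned slab in the middle
    tensors2 = tensors.copy()
    tensors2[20:22] = np.diag([2e-4, 1.7e-3, 2e-4])
    tf2 = TensorField.from_tensors(tensors2, voxel_size=(h, h, h))
    seeds = SeedRegion(voxels=np.argwhere(np.zeros(shape, bool) | (np.arange(shape[0])[:, None, None] < 5)))
    ss2 = fact_track(tf2, seeds, params)
    n_through = sum(1 for s in ss2.streamlines if s[:, 0].max() > 23 * h)
    return {
        "max_perpendicular_deviation_voxels": dev / h,
        "crossing_straight_through": int(n_through),
        "n_streamlines": len(ss),
    }


def conservation(seed: int = 0, n_fields: int = 10) -> dict:
    """Mass conservation of gridding, transfer (with particle oracle) and projection."""
    rng = np.random.default_rng(_seed(seed, "conserve"))
    size = 2560.0
    grid_err = transfer_err = tv_max = 0.0
    for k in range(n_fields):
        pts = rng.uniform(400, 2100, size=(4000, 2))
        ddm = grid_counts(pts, size)
        grid_err = max(grid_err, abs(ddm.total() - len(pts)))
        fld = make_deformation((2560, 2560), 60.0, _seed(seed, f"field{k}"))
        out = transfer_ddm(ddm, fld)
        transfer_err = max(transfer_err, abs(out.total() - ddm.total()) / ddm.total())
        oracle = grid_counts(fld.map_points(pts), size)
        a = out.counts.reshape(16, 16, 16, 16).sum(axis=(1, 3))
        b = oracle.counts.reshape(16, 16, 16, 16).sum(axis=(1, 3))
        tv = 0.5 * np.abs(a / a.sum() - b / b.sum()).sum()
        tv_max = max(tv_max, float(tv))
    # identity and uniform affine are exact
    ddm = grid_counts(rng.uniform(100, 1100, size=(2000, 2)), size)
    ident_err = abs(transfer_ddm(ddm, DeformationField.identity((256, 256))).total() - ddm.total())
    affine_err = abs(transfer_ddm(ddm, DeformationField.from_affine(2 * np.eye(2))).total() - ddm.total())
    # projection conservation on a phantom slab
    cfg = PhantomConfig()
    tissue, _ = make_phantom(cfg)
    interface = extract_interface(tissue.label_volume, cfg.voxel_size)
    dens = np.where(tissue.label_volume == GM, rng.uniform(0, 3, tissue.label_volume.shape), 0.0)
    proj = project_to_interface(dens, interface)
    proj_err = abs(proj.total() - dens.sum())
    return {
        "grid_counts_mass_error": float(grid_err),
        "transfer_max_rel_mass_error": float(transfer_err),
        "transfer_identity_error": float(ident_err),
        "transfer_affine_error": float(affine_err),
        "particle_oracle_tv_max": float(tv_max),
        "projection_mass_error": float(proj_err),
        "n_fields": n_fields,
    }


def tps_properties(seed: int = 0) -> dict:
    rng = np.random.default_rng(_seed(seed, "tps"))
    src = rng.uniform(0, 200, size=(40, 2))
    A = np.array([[1.15, 0.25], [-0.15, 0.92]])
    t = np.array([7.0, -4.0])
    fld = tps_fit(src, src @ A.T + t, 0.0)
    nonlin = float(np.abs(fld.nonlinear_weights).max())
    dst = src + rng.normal(0, 8, size=src.shape)
    fld2 = tps_fit(src, dst, 0.0)
    resid = float(np.abs(fld2.map_points(src) - dst).max())
    return {"affine_nonlinear_coeff_max": nonlin, "landmark_residual_px": resid}


def micrograph_counting(seed: int = 0, n_images: int = 20) -> dict:
    """Planted-truth counting on clean and noisy synthetic micrographs."""
    clean_dev = 0
    abs_dev = truth_total = 0
    shift_change = 0.0
    for k in range(n_images):
        m, truth = make_micrograph(rng_seed=_seed(seed, f"micro{k}"))
        objs = segment_fiber_objects(tophat_correct(m, 15))
        boundary = fit_boundary_curve(truth.boundary_markers, width=6)
        n = len(extract_crossing_fibers(objs, boundary))
        abs_dev += abs(n - truth.crossing_count)
        truth_total += truth.crossing_count
        lo, mid, hi = (
            len(extract_crossing_fibers(objs, boundary.shifted(off))) for off in (-50, 0, 50)
        )
        if mid:
            shift_change = max(shift_change, abs(lo - mid) / mid, abs(hi - mid) / mid)
        if k < 3:  # clean-image exactness probe
            mc, tc = make_micrograph(rng_seed=_seed(seed, f"clean{k}"), noise=0.0)
            oc = segment_fiber_objects(tophat_correct(mc, 15))
            bc = fit_boundary_curve(tc.boundary_markers, width=6)
            clean_dev = max(clean_dev, abs(len(extract_crossing_fibers(oc, bc)) - tc.crossing_count))
    return {
        "clean_max_abs_deviation": int(clean_dev),
        "noisy_total_deviation_pct": 100.0 * abs_dev / truth_total,
        "boundary_shift_max_change_pct": 100.0 * shift_change,
        "n_images": n_images,
    }


def stats_oracles(seed: int = 0, n_vectors: int = 1000) -> dict:
    """Definitional correlation implementations vs scipy, and intercept-CI coverage."""
    rng = np.random.default_rng(_seed(seed, "stats"))
    max_diff = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(5, 15))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        rp, _ = correlate(x, y, "pearson")
        rs, _ = correlate(x, y, "spearman")
        max_diff = max(max_diff, abs(rp - sps.pearsonr(x, y)[0]), abs(rs - sps.spearmanr(x, y)[0]))
        if n >= 12:
            rt, _, _ = topk_spearman(x - x.min(), y, rule="largest", k=10)
            sel = np.argsort(x)[::-1][:10]
            max_diff = max(max_diff, abs(rt - sps.spearmanr(x[sel], y[sel])[0]))
        rv, _, _ = voxelwise_pearson(x, y)
        max_diff = max(max_diff, abs(rv - sps.pearsonr(x, y)[0]))
    hits = 0
    n_rep = 1000
    for _ in range(n_rep):
        x = rng.uniform(10, 1000, size=12)
        y = 2.5 * x + rng.normal(0, 80, size=12)
        if fit_proportional(x, y).model_used == 2:
            hits += 1
    return {
        "correlation_oracle_max_abs_diff": float(max_diff),
        "origin_model_coverage_pct": 100.0 * hits / n_rep,
        "n_vectors": n_vectors,
    }


# ---------------------------------------------------------------------------
def _ds_regional_counts(tissue, tf, d_w_levels):
    cfg = tissue.config
    params = TrackingParams()
    streams = fact_track(tf, whole_brain_seeds(tf, params), params)
    interface = extract_interface(tissue.label_volume, cfg.voxel_size)
    roi_if = tissue.roi_label_map[tuple(interface.voxels.T)]
    wm = tissue.label_volume == WM
    out = {}
    for d_w in d_w_levels:
        sr = build_seed_region(tissue.injection_mask, interface, wm, d_w, cfg.voxel_size)
        band = _selection_band(tissue, interface, sr)
        sel = select_streamlines(streams, sr.voxels, band)
        nd = regional_counts(streamline_interface_ddm(sel, interface), roi_if)
        out[d_w] = nd
    return out


def end_to_end_recovery(seed: int = 0) -> dict:
    """Ground-truth axon-count recovery by deterministic tracking, with and
    without an occluding crossing bundle, across the d_w sweep."""
    scheme = make_scheme()
    results = {}
    for tag, crossing in (("free", None), ("crossing", CrossingSpec())):
        cfg = PhantomConfig(crossing_spec=crossing)
        tissue, ttrue = make_phantom(cfg)
        s0 = np.where(tissue.label_volume != 0, 1000.0, 50.0)
        dwi = simulate_dwi(ttrue, scheme, s0=s0,
                           noise_sigma=cfg.noise_sigma * 1000.0, rng_seed=_seed(seed, "e2e"))
        tf = fit_tensor(dwi, mask=tissue.label_volume != 0)
        counts = _ds_regional_counts(tissue, tf, (0.0, 0.3, 0.6))
        truth = {r: tissue.bundle_truth[r]["axon_count"] for r in sorted(tissue.bundle_truth)}
        conn = [r for r in truth if truth[r] > 0]
        results[tag] = {"truth": truth, "counts": counts, "conn": conn}

    free, cross = results["free"], results["crossing"]
    r06, _ = correlate(
        [free["truth"][r] for r in free["conn"]],
        [free["counts"][0.6][r] for r in free["conn"]],
    )
    fn_free = {d: sum(1 for r in free["conn"] if free["counts"][d][r] == 0) for d in (0.0, 0.3, 0.6)}
    fp_free = {d: sum(1 for r in free["truth"] if free["truth"][r] == 0 and free["counts"][d][r] > 0)
               for d in (0.0, 0.3, 0.6)}
    occ = CrossingSpec().blocked_roi
    fn_cross = {d: sum(1 for r in cross["conn"] if cross["counts"][d][r] == 0) for d in (0.0, 0.3, 0.6)}
    return {
        "pearson_r_nd_vs_axon_dw06": float(r06),
        "fn_free_dw06": fn_free[0.6],
        "fp_free_dw06": fp_free[0.6],
        "occluded_nd_free_dw0": float(free["counts"][0.0][occ]),
        "occluded_nd_crossing_dw0": float(cross["counts"][0.0][occ]),
        "fn_crossing_dw0": fn_cross[0.0],
        "fn_crossing_dw03": fn_cross[0.3],
        "fn_crossing_dw06": fn_cross[0.6],
    }


def determinism(seed: int = 0, workdir: str = "scratch/determinism") -> dict:
    """Byte-identical report bundles from two identical full runs."""
    base = Path(workdir)
    digests = []
    for tag in ("x", "y"):
        out = base / tag
        cfg = RunConfig(output_dir=str(out), rng_seed=seed)
        run_experiment(cfg)
        h = hashlib.sha256()
        for f in sorted(out.iterdir()):
            if f.name in ("config.yaml",):  # records the differing output path
                continue
            h.update(f.name.encode())
            h.update(f.read_bytes())
        digests.append(h.hexdigest())
    return {"byte_identical": float(digests[0] == digests[1])}
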