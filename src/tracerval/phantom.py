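"""Digital phantom with known cortico-cortical connectivity ground truth.

The phantom emulates the layout of the validation experiment: a flat cortical
slab (gray matter over white matter), an injection region on the slab, and a
ring of projection regions connected to the injection site by curved
white-matter bundles whose axon counts span several orders of magnitude.
Bundle voxels carry prolate diffusion tensors aligned with the local
centerline tangent; where two bundles overlap, the bundle with the larger
axon count wins the voxel outright (single-tensor partial-volume emulation,
the mechanism that defeats tractography in crossing-fiber regions).  An
optional orthogonal "crossing bar" occludes one pathway in the superficial
white matter beneath the injection, one to two voxels under the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .tensors import TensorField

__all__ = [
    "BACKGROUND",
    "WM",
    "GM",
    "BundleSpec",
    "CrossingSpec",
    "PhantomConfig",
    "TissueModel",
    "make_phantom",
    "make_ground_truth_fibers",
]

BACKGROUND, WM, GM = 0, 1, 2

# diffusion eigenvalues, mm^2/s
LAMBDA_BUNDLE = (1.7e-3, 0.21e-3, 0.21e-3)  # FA ~ 0.85
LAMBDA_WM_ISO = 0.75e-3
LAMBDA_GM = (0.85e-3, 0.68e-3, 0.68e-3)  # radially oriented, FA ~ 0.13

# default axon counts per projection region slot; 0 marks the silent region
# (anatomically unconnected, available as a false-positive probe). Counts span
# three orders of magnitude, mirroring the dynamic range of real tracer data.
DEFAULT_AXON_COUNTS = (15000, 2000, 50, 800, 0, 20, 6000, 300, 100)


@dataclass
class BundleSpec:
    """A white-matter bundle from the injection region to one projection ROI."""

    roi_id: int  # 1-based projection region id
    axon_count: int
    soma_count: int = None  # defaults to axon_count (reciprocal connectivity)
    radius_mm: float = None  # defaults to sqrt-scaling with axon count
    control_points: np.ndarray = None  # (n, 3) mm; defaults to ring geometry

    def __post_init__(self):
        if self.axon_count < 0:
            raise ValueError("axon_count must be >= 0")
        if self.soma_count is None:
            self.soma_count = self.axon_count
        if self.radius_mm is not None and self.radius_mm <= 0:
            raise ValueError("radius must be > 0")
        if self.control_points is not None:
            self.control_points = np.asarray(self.control_points, dtype=float)


@dataclass
class CrossingSpec:
    """Orthogonal occluding bar through one bundle's subcortical column.

    The bar runs tangentially (perpendicular to the blocked bundle's local
    direction) through the bundle's descent column, centred on the boundary
    between the first and second white-matter layers beneath the interface,
    so it occupies exactly the one-to-two-voxel depth range that the seed
    extension d_w = 0.3/0.6 mm can reach.
    """

    blocked_roi: int = 4
    axon_count: int = 30000
    radius_mm: float = 0.44
    half_length_mm: float = 0.6


@dataclass
class PhantomConfig:
    grid_shape: tuple = (64, 64, 64)
    voxel_size: tuple = (0.3, 0.3, 0.3)
    n_projection_rois: int = 9
    bundle_specs: list = None
    crossing_spec: Optional[CrossingSpec] = None
    noise_sigma: float = 1.0 / 25.0  # Rician scale relative to S0 (SNR ~ 25)
    rng_seed: int = 0
    # slab / ring geometry
    gm_start: int = 16  # first gray-matter z index
    gm_thickness: int = 4
    injection_radius_mm: float = 3.6
    roi_ring_radius_mm: float = 6.5
    roi_radius_mm: float = 1.5
    descent_ring_radius_mm: float = 2.2
    max_bundle_radius_mm: float = 1.0
    min_bundle_radius_mm: float = 0.32

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(n < 32 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 32 per axis")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.bundle_specs is None:
            self.bundle_specs = self._default_bundles()

    # -- derived geometry ---------------------------------------------------
    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.voxel_size)

    @property
    def centre_xy(self) -> np.ndarray:
        return self.extent_mm[:2] / 2.0

    def roi_angle(self, slot: int) -> float:
        return 2 * np.pi * slot / self.n_projection_rois

    def roi_centre(self, slot: int) -> np.ndarray:
        a = self.roi_angle(slot)
        return self.centre_xy + self.roi_ring_radius_mm * np.array([np.cos(a), np.sin(a)])

    def descent_point(self, slot: int) -> np.ndarray:
        a = self.roi_angle(slot)
        return self.centre_xy + self.descent_ring_radius_mm * np.array([np.cos(a), np.sin(a)])

    def bundle_radius(self, axon_count: int) -> float:
        ref = max(s.axon_count for s in self.bundle_specs) if self.bundle_specs else 1
        r = self.max_bundle_radius_mm * np.sqrt(axon_count / max(ref, 1))
        return float(max(self.min_bundle_radius_mm, r))

    def depth_voxels(self, slot: int) -> int:
        return 5 + slot  # staggered depths keep deep runs from colliding

    def _default_bundles(self) -> list:
        counts = DEFAULT_AXON_COUNTS[: self.n_projection_rois]
        if len(counts) < self.n_projection_rois:
            counts = tuple(counts) + (100,) * (self.n_projection_rois - len(counts))
        return [
            BundleSpec(roi_id=slot + 1, axon_count=c)
            for slot, c in enumerate(counts)
            if c > 0
        ]


@dataclass
class TissueModel:
    """Labelled phantom tissue with ground-truth connectivity bookkeeping."""

    label_volume: np.ndarray  # {BACKGROUND, WM, GM}
    injection_mask: np.ndarray  # bool
    roi_label_map: np.ndarray  # 0 = none, k = projection region k
    bundle_truth: dict  # roi_id -> {"axon_count": int, "soma_count": int}
    config: PhantomConfig
    bundle_id_map: np.ndarray = field(default=None, repr=False)  # 0 none, -1 crossing
    crossing_voxels: np.ndarray = field(default=None, repr=False)

    @property
    def voxel_size(self):
        return self.config.voxel_size

    @property
    def roi_ids(self):
        return sorted(int(k) for k in np.unique(self.roi_label_map) if k > 0)

    def voxel_centres_mm(self, index_array: np.ndarray) -> np.ndarray:
        return (np.asarray(index_array) + 0.5) * np.asarray(self.voxel_size)


def _smooth_polyline(points: np.ndarray, step: float, window: float) -> np.ndarray:
    """Densify a piecewise-linear path and round its corners by moving average."""
    segs = np.diff(points, axis=0)
    lens = np.linalg.norm(segs, axis=1)
    dense = [points[0]]
    for p0, seg, ln in zip(points[:-1], segs, lens):
        n = max(int(np.ceil(ln / step)), 1)
        t = np.arange(1, n + 1) / n
        dense.append(p0 + t[:, None] * seg)
    dense = np.vstack(dense)
    half = max(int(round(window / (2 * step))), 1)
    padded = np.vstack([dense[:1].repeat(half, axis=0), dense, dense[-1:].repeat(half, axis=0)])
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    smooth = np.column_stack(
        [np.convolve(padded[:, d], kernel, mode="valid") for d in range(3)]
    )
    return smooth


def _polyline_tangents(points: np.ndarray) -> np.ndarray:
    t = np.gradient(points, axis=0)
    n = np.linalg.norm(t, axis=1, keepdims=True)
    return t / np.where(n > 0, n, 1.0)


def _default_centerline(cfg: PhantomConfig, spec: BundleSpec) -> np.ndarray:
    slot = spec.roi_id - 1
    h = cfg.voxel_size[2]
    z_top = (cfg.gm_start + 1.5) * h  # inside injection / ROI gray matter
    z_deep = (cfg.gm_start - 0.5 - cfg.depth_voxels(slot)) * h
    dxy = cfg.descent_point(slot)
    rxy = cfg.roi_centre(slot)
    return np.array(
        [
            [dxy[0], dxy[1], z_top],
            [dxy[0], dxy[1], z_deep],
            [rxy[0], rxy[1], z_deep],
            [rxy[0], rxy[1], z_top],
        ]
    )


def _prolate_tensor(tangents: np.ndarray, lam) -> np.ndarray:
    l1, l2, _ = lam
    t = tangents
    return l2 * np.eye(3) + (l1 - l2) * np.einsum("...i,...j->...ij", t, t)


def make_phantom(config: PhantomConfig):
    """Build the labelled tissue volume and its diffusion tensor field.

    Returns ``(TissueModel, TensorField)``.  Deterministic for a given
    configuration: the construction is purely geometric.
    """
    cfg = config
    shape = tuple(cfg.grid_shape)
    h = np.asarray(cfg.voxel_size)
    nz_gm = cfg.gm_start + cfg.gm_thickness
    if nz_gm >= shape[2]:
        raise ValueError("gray matter slab does not fit in the grid")

    labels = np.full(shape, BACKGROUND, dtype=np.int16)
    labels[:, :, : cfg.gm_start] = WM
    labels[:, :, cfg.gm_start : nz_gm] = GM

    ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    xy = np.stack([(ii + 0.5) * h[0], (jj + 0.5) * h[1]], axis=-1)

    inj2d = np.linalg.norm(xy - cfg.centre_xy, axis=-1) <= cfg.injection_radius_mm
    injection_mask = np.zeros(shape, dtype=bool)
    injection_mask[:, :, cfg.gm_start : nz_gm] = inj2d[:, :, None]

    roi_label_map = np.zeros(shape, dtype=np.int16)
    for slot in range(cfg.n_projection_rois):
        roi2d = np.linalg.norm(xy - cfg.roi_centre(slot), axis=-1) <= cfg.roi_radius_mm
        if np.any(roi2d & inj2d):
            raise ValueError(f"projection ROI {slot + 1} overlaps the injection region")
        if np.any(roi_label_map[:, :, cfg.gm_start][roi2d] > 0):
            raise ValueError(f"projection ROI {slot + 1} overlaps another ROI")
        roi_label_map[:, :, cfg.gm_start : nz_gm][roi2d] = slot + 1

    # base tensors
    tensors = np.zeros(shape + (3, 3))
    tensors[labels == WM] = LAMBDA_WM_ISO * np.eye(3)
    gm_tensor = np.diag([LAMBDA_GM[1], LAMBDA_GM[2], LAMBDA_GM[0]])  # radial = z
    tensors[labels == GM] = gm_tensor

    wm_idx = np.argwhere(labels == WM)
    wm_centres = (wm_idx + 0.5) * h
    tree = cKDTree(wm_centres)

    owner_ac = np.full(shape, -1, dtype=np.int64)
    bundle_id_map = np.zeros(shape, dtype=np.int16)
    extent = cfg.extent_mm

    def paint(samples, tangents, radius, ac, bid, name):
        if np.any(samples < 0) or np.any(samples >= extent):
            raise ValueError(f"bundle {name} leaves the phantom grid")
        stree = cKDTree(samples)
        hits = tree.query_ball_tree(stree, r=radius)
        for vox_row, sample_ids in enumerate(hits):
            if not sample_ids:
                continue
            i, j, k = wm_idx[vox_row]
            if owner_ac[i, j, k] >= ac:
                continue
            d = np.linalg.norm(samples[sample_ids] - wm_centres[vox_row], axis=1)
            t = tangents[sample_ids[int(np.argmin(d))]]
            tensors[i, j, k] = _prolate_tensor(t, LAMBDA_BUNDLE)
            owner_ac[i, j, k] = ac
            bundle_id_map[i, j, k] = bid

    bundle_truth = {}
    for spec in cfg.bundle_specs:
        slot = spec.roi_id - 1
        if slot < 0 or slot >= cfg.n_projection_rois:
            raise ValueError(f"bundle targets unknown ROI {spec.roi_id}")
        bundle_truth[spec.roi_id] = {
            "axon_count": int(spec.axon_count),
            "soma_count": int(spec.soma_count),
        }
        pts = spec.control_points
        if pts is None:
            pts = _default_centerline(cfg, spec)
        samples = _smooth_polyline(np.asarray(pts, dtype=float), step=0.06, window=1.0)
        tangents = _polyline_tangents(samples)
        radius = spec.radius_mm or cfg.bundle_radius(spec.axon_count)
        paint(samples, tangents, radius, spec.axon_count, spec.roi_id, f"ROI {spec.roi_id}")

    # silent regions (no bundle) still need truth entries
    for slot in range(cfg.n_projection_rois):
        bundle_truth.setdefault(slot + 1, {"axon_count": 0, "soma_count": 0})

    crossing_voxels = np.zeros(shape, dtype=bool)
    if cfg.crossing_spec is not None:
        cs = cfg.crossing_spec
        if cs.blocked_roi not in {s.roi_id for s in cfg.bundle_specs}:
            raise ValueError("crossing_spec.blocked_roi has no bundle to occlude")
        slot = cs.blocked_roi - 1
        a = cfg.roi_angle(slot)
        tangential = np.array([-np.sin(a), np.cos(a), 0.0])
        centre = np.array(
            [*cfg.descent_point(slot), (cfg.gm_start - 1) * h[2]]
        )  # boundary between the two superficial WM layers
        s = np.linspace(-cs.half_length_mm, cs.half_length_mm, 41)
        samples = centre + s[:, None] * tangential
        tangents = np.broadcast_to(tangential, samples.shape).copy()
        paint(samples, tangents, cs.radius_mm, cs.axon_count, -1, "crossing bar")
        crossing_voxels = bundle_id_map == -1

    tissue = TissueModel(
        label_volume=labels,
        injection_mask=injection_mask,
        roi_label_map=roi_label_map,
        bundle_truth=bundle_truth,
        config=cfg,
        bundle_id_map=bundle_id_map,
        crossing_voxels=crossing_voxels,
    )
    tf = TensorField.from_tensors(tensors, mask=labels != BACKGROUND, voxel_size=tuple(cfg.voxel_size))
    return tissue, tf


def make_ground_truth_fibers(
    tissue: TissueModel,
    rng_seed: int,
    micrograph_um_per_px: float = 7.5,
    spread_mm: float = 0.8,
):
    """Ground-truth tracer observations with exact per-region totals.

    For each projection region, places exactly ``axon_count`` fiber centroids
    in micrograph-space pixel coordinates under the region's interface
    footprint (truncated-Gaussian spread around the region centre) and
    ``soma_count`` soma positions (mm) inside the region's gray matter.

    Returns ``(fiber_centroids_px, soma_positions_mm)``: dicts keyed by ROI id.
    """
    cfg = tissue.config
    rng = np.random.default_rng(rng_seed)
    px_per_mm = 1000.0 / micrograph_um_per_px
    h = np.asarray(cfg.voxel_size)
    margin = 0.18 * min(h[0], h[1])  # keeps every centroid's grid cell inside its column

    fibers, somas = {}, {}
    for roi_id in sorted(tissue.bundle_truth):
        cols = np.argwhere(tissue.roi_label_map[:, :, cfg.gm_start] == roi_id)
        if len(cols) == 0:
            raise ValueError(f"ROI {roi_id} has no interface voxels")
        truth = tissue.bundle_truth[roi_id]
        centre = cfg.roi_centre(roi_id - 1)
        col_xy = (cols + 0.5) * h[:2]
        w = np.exp(-np.sum((col_xy - centre) ** 2, axis=1) / (2 * spread_mm**2))
        w /= w.sum()

        def scatter(n):
            # pick a voxel column (Gaussian-weighted), then a position inside
            # it, inset so the point's DDM cell centre stays in the column
            pick = rng.choice(len(cols), size=n, p=w)
            off = rng.uniform(margin, h[:2] - margin, size=(n, 2))
            return cols[pick] * h[:2] + off

        fibers[roi_id] = scatter(truth["axon_count"]) * px_per_mm
        xy = scatter(truth["soma_count"])
        z = (cfg.gm_start + rng.uniform(0, cfg.gm_thickness, size=len(xy))) * h[2]
        somas[roi_id] = np.column_stack([xy, z])
    return fibers, somas
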