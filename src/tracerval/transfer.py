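"""Carrying density maps between spaces with mass preservation.

Three pieces: a thin-plate-spline 2D landmark warp (the section-to-block
registration step), Jacobian-determinant-compensated density resampling (so
that transported DDMs keep their integrated counts), and projection of
gray-matter densities onto the 3D white/gray-matter interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .deformation import DeformationField
from .histology import DDM2D

__all__ = [
    "InterfaceSet",
    "SurfaceDDM",
    "extract_interface",
    "tps_fit",
    "transfer_ddm",
    "project_to_interface",
    "bin_positions_volume",
    "plane_density_to_interface",
]

log = logging.getLogger(__name__)


@dataclass
class InterfaceSet:
    """Ordered voxel set on the white/gray-matter interface.

    Interface voxels are gray-matter voxels 6-adjacent to at least one
    white-matter voxel, listed in ascending linear-index order (the
    deterministic tie-break order for nearest-voxel assignment).
    """

    voxels: np.ndarray  # (n, 3) int indices
    shape: tuple
    voxel_size: tuple
    normals: np.ndarray = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=int).reshape(-1, 3)
        order = np.lexsort((self.voxels[:, 2], self.voxels[:, 1], self.voxels[:, 0]))
        self.voxels = self.voxels[order]
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)[order]

    def __len__(self):
        return len(self.voxels)

    def centres_mm(self) -> np.ndarray:
        return (self.voxels + 0.5) * np.asarray(self.voxel_size)

    def linear_indices(self) -> np.ndarray:
        return np.ravel_multi_index(self.voxels.T, self.shape)

    def index_map(self) -> np.ndarray:
        """Full-volume map: voxel -> position in ``voxels`` (-1 elsewhere)."""
        m = np.full(self.shape, -1, dtype=int)
        m[tuple(self.voxels.T)] = np.arange(len(self.voxels))
        return m


@dataclass
class SurfaceDDM:
    """Nonnegative density per interface voxel."""

    density: np.ndarray  # (n,), aligned with interface.voxels
    interface: InterfaceSet
    provenance: str  # bda_fiber | bda_soma | ds_stream | ds_terminal | prob_stream
    unassigned: float = 0.0  # mass that mapped to no interface voxel

    def __post_init__(self):
        d = np.asarray(self.density, dtype=float)
        if d.shape != (len(self.interface),):
            raise ValueError("density must align with the interface voxel list")
        if np.any(d < -1e-12):
            raise ValueError("density must be nonnegative")
        self.density = np.clip(d, 0.0, None)

    def total(self) -> float:
        return float(self.density.sum())

    def as_volume(self) -> np.ndarray:
        v = np.zeros(self.interface.shape)
        v[tuple(self.interface.voxels.T)] = self.density
        return v


def extract_interface(label_volume: np.ndarray, voxel_size, wm_label: int = 1, gm_label: int = 2) -> InterfaceSet:
    """GM voxels 6-adjacent to WM, with outward (WM -> GM) normals."""
    gm = label_volume == gm_label
    wm = label_volume == wm_label
    struct = ndimage.generate_binary_structure(3, 1)
    wm_adjacent = ndimage.binary_dilation(wm, structure=struct) & gm
    vox = np.argwhere(wm_adjacent)
    if len(vox) == 0:
        raise ValueError("label volume has no white/gray interface")
    # normal: mean direction away from adjacent WM neighbours
    offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    normals = np.zeros((len(vox), 3))
    shape = label_volume.shape
    for off in offsets:
        nb = vox + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        is_wm = np.zeros(len(vox), dtype=bool)
        is_wm[ok] = wm[tuple(nb[ok].T)]
        normals[is_wm] -= off
    nrm = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, nrm, out=np.zeros_like(normals), where=nrm > 0)
    return InterfaceSet(voxels=vox, shape=shape, voxel_size=tuple(voxel_size), normals=normals)


# ---------------------------------------------------------------------------
# thin-plate spline


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(r2 > 0, 0.5 * r2 * np.log(r2), 0.0)  # r^2 log r


def tps_fit(source_landmarks: np.ndarray, target_landmarks: np.ndarray, regularization: float = 0.0) -> DeformationField:
    """Classic 2D thin-plate-spline landmark warp.

    Minimizes bending energy subject to (regularized) interpolation of the
    landmark correspondences; at ``regularization = 0`` each source landmark
    maps exactly onto its target.  The Jacobian is evaluated analytically
    from the spline coefficients.  The returned field's ``nonlinear_weights``
    attribute exposes the radial-basis coefficients (zero for purely affine
    correspondences, the affine-reproduction property).
    """
    src = np.asarray(source_landmarks, dtype=float).reshape(-1, 2)
    dst = np.asarray(target_landmarks, dtype=float).reshape(-1, 2)
    if src.shape != dst.shape:
        raise ValueError("source and target landmark counts differ")
    n = len(src)
    if n < 3:
        raise ValueError("need at least 3 landmark pairs")
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    spread = np.linalg.svd(src - src.mean(axis=0), compute_uv=False)
    if regularization == 0 and (spread.min() < 1e-9 * max(spread.max(), 1.0)):
        raise ValueError("collinear landmarks need regularization > 0")

    d2 = np.sum((src[:, None, :] - src[None, :, :]) ** 2, axis=-1)
    K = _tps_kernel(d2) + regularization * np.eye(n)
    P = np.column_stack([np.ones(n), src])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = dst
    try:
        coef = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "degenerate landmark configuration (collinear landmarks need regularization > 0)"
        ) from exc
    W = coef[:n]  # (n, 2) radial weights
    affine = coef[n:]  # rows: [c; ax; ay] per output dim

    span = max(float(np.ptp(src[:, 0])), float(np.ptp(src[:, 1])), 1.0)
    shape = (int(np.ceil(span)) + 1,) * 2

    def disp(points):
        pts = np.atleast_2d(points)
        r2 = np.sum((pts[:, None, :] - src[None, :, :]) ** 2, axis=-1)
        mapped = _tps_kernel(r2) @ W + np.column_stack([np.ones(len(pts)), pts]) @ affine
        return mapped - pts

    def jac(points):
        pts = np.atleast_2d(points)
        diff = pts[:, None, :] - src[None, :, :]  # (m, n, 2)
        r2 = np.sum(diff**2, axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            dkern = np.where(r2 > 0, np.log(r2) + 1.0, 0.0)  # d(r^2 log r)/dx = x~ (2 log r + 1)
        grad = dkern[..., None] * diff  # (m, n, 2): gradient of kernel wrt x
        J = np.einsum("mnj,ni->mij", grad, W)  # (m, 2out, 2in)
        J += affine[1:, :].T[None, :, :]
        return J

    fld = DeformationField(
        ndim=2, shape=shape, displacement_fn=disp, jacobian_fn=jac,
        source_space="micrograph", target_space="block",
    )
    fld.nonlinear_weights = W
    return fld


# ---------------------------------------------------------------------------
# density transfer


def transfer_ddm(ddm, fld: DeformationField, out_shape=None):
    """Resample a density through a deformation with Jacobian compensation.

    The forward map carries source points to target points; the output grid is
    filled by pulling each target cell centre back through the (Newton-
    inverted) map, interpolating the source density there, and multiplying by
    ``1 / det J_phi`` so that integrated counts are preserved.  Accepts a
    ``DDM2D`` (grid-cell units handled internally) or a plain array density.
    Chained transfers compose: compensation is applied at every step.
    """
    if isinstance(ddm, DDM2D):
        counts = ddm.counts
        unit = ddm.unit_size
        ndim = 2
    else:
        counts = np.asarray(ddm, dtype=float)
        unit = 1.0
        ndim = counts.ndim
    if fld.ndim != ndim:
        raise ValueError("field dimensionality does not match the density")
    out_shape = tuple(out_shape) if out_shape is not None else counts.shape

    axes = [np.arange(n, dtype=float) for n in out_shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    centres = (np.stack([m.ravel() for m in mesh], axis=-1) + 0.5) * unit
    src_pts = fld.inverse_points(centres)
    det = fld.jacobian_det_at(src_pts)

    cell_coords = (src_pts / unit - 0.5).T  # index-space coordinates
    vals = ndimage.map_coordinates(counts, cell_coords, order=1, mode="constant", cval=0.0)
    support = vals > 0
    if np.any(det[support] <= 0):
        raise ValueError("deformation has nonpositive Jacobian determinant in the density support")
    out = (vals / np.where(det > 0, det, 1.0)).reshape(out_shape)
    out[out < 0] = 0.0
    if isinstance(ddm, DDM2D):
        return DDM2D(
            counts=out, unit_size=unit, image_size=out_shape[0] * unit,
            space_tag=fld.target_space, provenance=ddm.provenance,
        )
    return out


def transfer_particles(points: np.ndarray, fld: DeformationField) -> np.ndarray:
    """Push individual centroids through the forward map (test oracle path)."""
    return fld.map_points(points)


def project_to_interface(density_volume: np.ndarray, interface: InterfaceSet) -> SurfaceDDM:
    """Add every voxel's density to its nearest interface voxel.

    Distances are Euclidean between voxel centres; ties go to the interface
    voxel with the smallest linear index.  Total mass is preserved exactly.
    """
    if len(interface) == 0:
        raise ValueError("empty interface")
    dens = np.asarray(density_volume, dtype=float)
    if dens.shape != interface.shape:
        raise ValueError("density volume shape does not match the interface volume")
    src = np.argwhere(dens != 0)
    out = np.zeros(len(interface))
    if len(src):
        h = np.asarray(interface.voxel_size)
        tree = cKDTree(interface.centres_mm())
        pts = (src + 0.5) * h
        k = min(4, len(interface))
        dist, idx = tree.query(pts, k=k)
        dist = np.atleast_2d(dist.T).T
        idx = np.atleast_2d(idx.T).T
        tie = dist <= dist[:, :1] + 1e-9
        masked = np.where(tie, idx, len(interface) + 1)
        chosen = masked.min(axis=1)  # voxels list is sorted by linear index
        np.add.at(out, chosen, dens[tuple(src.T)])
    return SurfaceDDM(density=out, interface=interface, provenance="projected")


def bin_positions_volume(positions_mm: np.ndarray, shape, voxel_size) -> np.ndarray:
    """Bin 3D point positions (mm) into a per-voxel count volume."""
    pts = np.asarray(positions_mm, dtype=float).reshape(-1, 3)
    h = np.asarray(voxel_size)
    idx = np.floor(pts / h).astype(int)
    idx = np.clip(idx, 0, np.asarray(shape) - 1)
    vol = np.zeros(shape)
    np.add.at(vol, tuple(idx.T), 1.0)
    return vol


def plane_density_to_interface(
    ddm: DDM2D, interface: InterfaceSet, px_per_mm: float, provenance: str = "bda_fiber"
) -> SurfaceDDM:
    """Assign an interface-plane DDM directly to interface voxels.

    Each grid cell's count is added to the interface voxel in the (x, y)
    column under the cell centre (smallest linear index when a column holds
    several interface voxels).  Mass landing in columns without an interface
    voxel is reported in ``unassigned`` and logged.
    """
    h = np.asarray(interface.voxel_size)
    centres_px = ddm.cell_centres_px().reshape(-1, 2)
    counts = ddm.counts.ravel()
    nz = counts > 0
    cols = np.floor(centres_px[nz] / px_per_mm / h[:2]).astype(int)

    # first interface voxel per (x, y) column (voxels are sorted by linear index)
    col_map = np.full(interface.shape[:2], -1, dtype=int)
    vox = interface.voxels
    for pos in range(len(vox) - 1, -1, -1):
        col_map[vox[pos, 0], vox[pos, 1]] = pos

    out = np.zeros(len(interface))
    unassigned = 0.0
    ok = np.all((cols >= 0) & (cols < np.asarray(interface.shape[:2])), axis=1)
    tgt = np.full(len(cols), -1, dtype=int)
    tgt[ok] = col_map[cols[ok, 0], cols[ok, 1]]
    hit = tgt >= 0
    np.add.at(out, tgt[hit], counts[nz][hit])
    unassigned = float(counts[nz][~hit].sum())
    if unassigned:
        log.info("plane-to-interface: %.3g counts fell outside interface columns", unassigned)
    return SurfaceDDM(density=out, interface=interface, provenance=provenance, unassigned=unassigned)
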