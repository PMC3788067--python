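"""Smooth invertible deformation fields with analytic Jacobians.

These fields stand in for the registration chain that carries density maps
between histology and diffusion-image space: a 2D warp per section plus a 3D
block-to-volume warp.  Each field is a forward map ``phi(x) = x + u(x)`` whose
displacement ``u`` and full Jacobian matrix are available analytically at
arbitrary points, which is what mass-preserving density transfer needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["DeformationField", "make_deformation"]


def _as_points(points: np.ndarray, ndim: int) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[-1] != ndim:
        raise ValueError(f"expected points with {ndim} components, got shape {pts.shape}")
    return pts


@dataclass
class DeformationField:
    """Forward map ``phi(x) = x + u(x)`` on a rectangular domain.

    Parameters
    ----------
    ndim:
        Dimensionality, 2 or 3.
    shape:
        Grid shape of the domain (used for sampled ``displacement`` /
        ``jacobian_det`` arrays and for invertibility checks).
    displacement_fn:
        Callable mapping ``(n, ndim)`` points to displacements.
    jacobian_fn:
        Callable mapping ``(n, ndim)`` points to ``(n, ndim, ndim)`` Jacobian
        matrices of *phi* (including the identity part).
    source_space, target_space:
        Free-form provenance tags.
    """

    ndim: int
    shape: tuple
    displacement_fn: Callable[[np.ndarray], np.ndarray]
    jacobian_fn: Callable[[np.ndarray], np.ndarray]
    source_space: str = "source"
    target_space: str = "target"
    displacement: np.ndarray = field(default=None, repr=False)
    jacobian_det: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.ndim not in (2, 3):
            raise ValueError("only 2D and 3D fields are supported")
        if self.displacement is None or self.jacobian_det is None:
            grid = self._grid_points()
            probe_shape = tuple(min(int(n), 48) for n in self.shape)
            if self.displacement is None:
                self.displacement = self.displacement_fn(grid).reshape(
                    probe_shape + (self.ndim,)
                )
            if self.jacobian_det is None:
                self.jacobian_det = np.linalg.det(self.jacobian_fn(grid)).reshape(probe_shape)

    def _grid_points(self) -> np.ndarray:
        # sampled arrays use a probe grid decimated to <= 48 points per axis;
        # the analytic callables are exact everywhere
        axes = [np.linspace(0, n - 1, min(int(n), 48)) for n in self.shape]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    # -- evaluation ---------------------------------------------------------
    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        return self.displacement_fn(_as_points(points, self.ndim))

    def map_points(self, points: np.ndarray) -> np.ndarray:
        pts = _as_points(points, self.ndim)
        return pts + self.displacement_fn(pts)

    def jacobian_at(self, points: np.ndarray) -> np.ndarray:
        return self.jacobian_fn(_as_points(points, self.ndim))

    def jacobian_det_at(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.det(self.jacobian_at(points))

    def inverse_points(self, targets: np.ndarray, tol: float = 1e-10, maxiter: int = 50) -> np.ndarray:
        """Solve ``phi(x) = y`` for each target ``y`` by Newton iteration."""
        y = _as_points(targets, self.ndim)
        x = y - self.displacement_fn(y)  # first-order guess
        for _ in range(maxiter):
            r = x + self.displacement_fn(x) - y
            if np.max(np.abs(r)) < tol:
                break
            J = self.jacobian_fn(x)
            x = x - np.linalg.solve(J, r[..., None])[..., 0]
        return x

    def inverse(self) -> "DeformationField":
        """Field whose forward map is the Newton inverse of this one."""
        outer = self

        def disp(points):
            return outer.inverse_points(points) - points

        def jac(points):
            x = outer.inverse_points(points)
            return np.linalg.inv(outer.jacobian_fn(x))

        return DeformationField(
            ndim=outer.ndim,
            shape=outer.shape,
            displacement_fn=disp,
            jacobian_fn=jac,
            source_space=outer.target_space,
            target_space=outer.source_space,
        )

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity(cls, shape) -> "DeformationField":
        shape = tuple(shape)
        ndim = len(shape)

        def disp(points):
            return np.zeros_like(points)

        def jac(points):
            return np.broadcast_to(np.eye(ndim), (len(points), ndim, ndim)).copy()

        return cls(ndim=ndim, shape=shape, displacement_fn=disp, jacobian_fn=jac)

    @classmethod
    def from_affine(cls, matrix, offset=None, shape=None) -> "DeformationField":
        A = np.asarray(matrix, dtype=float)
        ndim = A.shape[0]
        t = np.zeros(ndim) if offset is None else np.asarray(offset, dtype=float)
        if shape is None:
            shape = (2,) * ndim

        def disp(points):
            return points @ A.T + t - points

        def jac(points):
            return np.broadcast_to(A, (len(points), ndim, ndim)).copy()

        return cls(ndim=ndim, shape=tuple(shape), displacement_fn=disp, jacobian_fn=jac)


def make_deformation(
    grid_shape,
    amplitude: float,
    rng_seed: int,
    n_modes: int = 3,
    min_jacobian: float = 0.2,
) -> DeformationField:
    """Random smooth displacement field as a sum of low-frequency sine modes.

    ``amplitude`` is the maximum displacement magnitude in grid units (pixels
    for 2D micrograph-space fields, voxels/mm for 3D ones, depending on the
    caller's convention).  The analytic Jacobian is assembled from the mode
    derivatives; a field whose Jacobian determinant drops to ``min_jacobian``
    or below anywhere on the grid is rejected with an error.
    """
    shape = tuple(int(n) for n in grid_shape)
    ndim = len(shape)
    if ndim not in (2, 3):
        raise ValueError("grid_shape must be 2D or 3D")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    extent = np.asarray(shape, dtype=float)
    rng = np.random.default_rng(rng_seed)

    # each mode: u_c(x) = a * prod_d sin(pi * k_d * x_d / L_d + phase_d)
    n_terms = n_modes * ndim
    ks = rng.integers(1, 4, size=(n_terms, ndim)).astype(float)
    phases = rng.uniform(0, 2 * np.pi, size=(n_terms, ndim))
    amps = rng.normal(size=(n_terms, ndim))

    def _raw_disp(points):
        args = np.pi * points[:, None, :] * ks / extent + phases  # (n, t, d)
        prod = np.prod(np.sin(args), axis=-1)  # (n, t)
        return prod @ amps  # (n, d)

    # normalise so that the max displacement on the grid equals `amplitude`
    axes = [np.linspace(0, n - 1, min(n, 24)) for n in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    probe = np.stack([m.ravel() for m in mesh], axis=-1)
    raw_max = np.max(np.linalg.norm(_raw_disp(probe), axis=1))
    scale = 0.0 if raw_max == 0 else amplitude / raw_max

    def disp(points):
        return scale * _raw_disp(points)

    def jac(points):
        pts = np.atleast_2d(points)
        args = np.pi * pts[:, None, :] * ks / extent + phases  # (n, t, d)
        sins = np.sin(args)
        coss = np.cos(args)
        J = np.zeros((len(pts), ndim, ndim))
        for j in range(ndim):  # derivative axis
            dprod = coss[:, :, j] * (np.pi * ks[:, j] / extent[j])
            for d in range(ndim):
                if d != j:
                    dprod = dprod * sins[:, :, d]
            J[:, :, j] = scale * (dprod @ amps)
        J += np.eye(ndim)
        return J

    fld = DeformationField(ndim=ndim, shape=shape, displacement_fn=disp, jacobian_fn=jac)
    min_det = float(np.min(fld.jacobian_det))
    if min_det <= min_jacobian:
        raise ValueError(
            f"amplitude {amplitude} yields a non-invertible field "
            f"(min Jacobian determinant {min_det:.4f} <= {min_jacobian})"
        )
    return fld
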