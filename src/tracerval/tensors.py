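"""Single-tensor model: log-linear fitting, FA, and PPD reorientation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dwi import DWIVolume

__all__ = ["TensorField", "fa_from_eigenvalues", "fit_tensor", "ppd_reorient"]

log = logging.getLogger(__name__)

# symmetric 6-component ordering used for NIfTI export: Dxx Dxy Dxz Dyy Dyz Dzz
SYM6_INDEX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


@dataclass
class TensorField:
    """Per-voxel diffusion tensor with derived FA and principal direction.

    ``tensor`` has shape (x, y, z, 3, 3) in mm^2/s; ``fa`` in [0, 1];
    ``principal_direction`` unit vectors (first nonzero component made
    nonnegative, so comparisons are deterministic); ``mask`` flags voxels with
    valid fits. ``eigenvalues`` are sorted descending.
    """

    tensor: np.ndarray
    fa: np.ndarray
    principal_direction: np.ndarray
    mask: np.ndarray
    eigenvalues: np.ndarray = None
    voxel_size: tuple = (1.0, 1.0, 1.0)
    negative_eigenvalue_mask: np.ndarray = field(default=None, repr=False)

    @property
    def shape(self):
        return self.tensor.shape[:3]

    @classmethod
    def from_tensors(cls, tensors: np.ndarray, mask=None, voxel_size=(1.0, 1.0, 1.0)) -> "TensorField":
        tensors = np.asarray(tensors, dtype=float)
        if mask is None:
            mask = np.ones(tensors.shape[:-2], dtype=bool)
        evals, evecs = np.linalg.eigh(tensors)
        evals = evals[..., ::-1]
        evecs = evecs[..., ::-1]
        pd = _canonical_sign(evecs[..., :, 0])
        fa = fa_from_eigenvalues(evals)
        return cls(
            tensor=tensors,
            fa=fa,
            principal_direction=pd,
            mask=np.asarray(mask, dtype=bool),
            eigenvalues=evals,
            voxel_size=tuple(voxel_size),
            negative_eigenvalue_mask=np.min(evals, axis=-1) < 0,
        )


def _canonical_sign(vectors: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip each vector so its first component of magnitude > tol is >= 0."""
    v = np.array(vectors, dtype=float)
    sign = np.zeros(v.shape[:-1])
    for k in range(v.shape[-1]):
        comp = v[..., k]
        use = (sign == 0) & (np.abs(comp) > tol)
        sign = np.where(use, np.sign(comp), sign)
    sign = np.where(sign == 0, 1.0, sign)
    return v * sign[..., None]


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from (possibly unsorted) eigenvalues.

    Negative eigenvalues (Rician-noise artifacts of the linear fit) are
    clamped at zero before evaluating the formula; an all-zero triple maps to
    FA = 0.
    """
    lam = np.clip(np.asarray(evals, dtype=float), 0.0, None)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sum((lam - mean) ** 2, axis=-1)
    den = np.sum(lam**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0))
    return np.clip(fa, 0.0, 1.0)


def fit_tensor(dwi: DWIVolume, mask: np.ndarray = None, signal_floor: float = 1e-6) -> TensorField:
    """Ordinary least-squares log-linear tensor fit.

    Solves ``ln S = ln S0 - b g^T D g`` per voxel.  The signal is clamped at
    ``signal_floor * S0`` before the log (the Rician floor can produce values
    near zero).  Voxels with non-finite signal are dropped from the mask with
    a logged count.
    """
    scheme = dwi.scheme
    if len(scheme) < 7:
        raise ValueError("need at least 7 acquisitions (1 b0 + 6 directions)")
    sig = dwi.signal
    shape = sig.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool).copy()

    finite = np.all(np.isfinite(sig), axis=-1)
    n_dropped = int(np.count_nonzero(mask & ~finite))
    if n_dropped:
        log.warning("dropping %d voxels with non-finite signal from the fit mask", n_dropped)
        mask &= finite

    b = scheme.b_values
    g = scheme.gradient_directions
    # design: ln S = X @ [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]
    X = np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    pinv = np.linalg.pinv(X)

    vox = sig[mask]  # (n_vox, n_acq)
    s0 = vox[:, b == 0].mean(axis=1)
    s0 = np.where(s0 > 0, s0, 1.0)
    clamped = np.maximum(vox, signal_floor * s0[:, None])
    beta = np.log(clamped) @ pinv.T  # (n_vox, 7)

    D = np.zeros((len(beta), 3, 3))
    D[:, 0, 0] = beta[:, 1]
    D[:, 1, 1] = beta[:, 2]
    D[:, 2, 2] = beta[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = beta[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = beta[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = beta[:, 6]

    tensors = np.zeros(shape + (3, 3))
    tensors[mask] = D
    out = TensorField.from_tensors(tensors, mask=mask, voxel_size=dwi.voxel_size)
    out.fa[~mask] = 0.0
    n_neg = int(np.count_nonzero(out.negative_eigenvalue_mask & mask))
    if n_neg:
        log.info("fit produced %d voxels with negative eigenvalues (flagged, retained)", n_neg)
    return out


def ppd_reorient(tensor: np.ndarray, local_affine: np.ndarray) -> np.ndarray:
    """Reorient a tensor under a local affine by preservation of principal direction.

    The output keeps the input eigenvalues; its first eigenvector is the
    normalized image of the input's first eigenvector under ``local_affine``
    and its second is the Gram-Schmidt correction of the image of the second.
    """
    D = np.asarray(tensor, dtype=float)
    F = np.asarray(local_affine, dtype=float)
    if abs(np.linalg.det(F)) < 1e-12:
        raise ValueError("local affine is singular")
    evals, evecs = np.linalg.eigh(D)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    n1 = F @ evecs[:, 0]
    n1 = n1 / np.linalg.norm(n1)
    v2 = F @ evecs[:, 1]
    n2 = v2 - (n1 @ v2) * n1
    norm2 = np.linalg.norm(n2)
    if norm2 < 1e-14:  # degenerate image; fall back to any perpendicular
        n2 = np.linalg.svd(np.outer(n1, n1) - np.eye(3))[0][:, 0]
    else:
        n2 = n2 / norm2
    n3 = np.cross(n1, n2)
    R = np.column_stack([n1, n2, n3])
    return R @ np.diag(evals) @ R.T
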