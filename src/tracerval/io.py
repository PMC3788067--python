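"""File formats: NIfTI volumes, FSL-style bval/bvec, TrackVis streamlines, TSV tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dwi import DiffusionScheme, DWIVolume
from .tensors import SYM6_INDEX

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_tensor_nifti",
    "save_bvals_bvecs",
    "load_bvals_bvecs",
    "save_dwi",
    "save_trk",
    "save_tsv",
    "save_surface_ddm_tsv",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size[:3]
    return aff


def save_nifti(data: np.ndarray, voxel_size, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size))
    nib.save(img, str(path))
    return path


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def save_tensor_nifti(tensors: np.ndarray, voxel_size, path) -> Path:
    """6-component symmetric ordering Dxx, Dxy, Dxz, Dyy, Dyz, Dzz."""
    t = np.asarray(tensors)
    six = np.stack([t[..., i, j] for i, j in SYM6_INDEX], axis=-1)
    return save_nifti(six, voxel_size, path)


def save_bvals_bvecs(scheme: DiffusionScheme, bval_path, bvec_path):
    np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.gradient_directions.T, fmt="%.8f")


def load_bvals_bvecs(bval_path, bvec_path) -> DiffusionScheme:
    b = np.loadtxt(bval_path).ravel()
    g = np.loadtxt(bvec_path)
    if g.shape[0] == 3:
        g = g.T
    return DiffusionScheme(b_values=b, gradient_directions=g)


def save_dwi(dwi: DWIVolume, prefix) -> Path:
    prefix = Path(prefix)
    save_nifti(dwi.signal, dwi.voxel_size, prefix.with_suffix(".nii"))
    save_bvals_bvecs(dwi.scheme, prefix.parent / (prefix.name + ".bval"),
                     prefix.parent / (prefix.name + ".bvec"))
    return prefix.with_suffix(".nii")


def save_trk(streamline_set, path) -> Path:
    from nibabel.streamlines import Tractogram, save as trk_save
    from nibabel.streamlines.trk import TrkFile

    path = Path(path)
    tg = Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamline_set.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    header = TrkFile.create_empty_header()
    trk_save(TrkFile(tg, header=header), str(path))
    return path


def save_tsv(frame: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g", lineterminator="\n")
    return path


def save_surface_ddm_tsv(sddm, path) -> Path:
    vox = sddm.interface.voxels
    frame = pd.DataFrame(
        {
            "i": vox[:, 0],
            "j": vox[:, 1],
            "k": vox[:, 2],
            "linear_index": sddm.interface.linear_indices(),
            "density": sddm.density,
        }
    )
    return save_tsv(frame, path, index=False)
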