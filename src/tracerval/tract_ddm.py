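"""Convert tracking output into interface densities.

Three densities are produced: distinct-streamline crossing counts per
interface voxel, streamline-terminal counts (terminals falling in projection
gray matter, assigned to the nearest interface voxel), and the restriction of
a probabilistic visitation map to the interface.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .tracking import StreamlineSet
from .transfer import InterfaceSet, SurfaceDDM

__all__ = [
    "streamline_voxels",
    "streamline_interface_ddm",
    "terminal_ddm",
    "probabilistic_interface_ddm",
]


def streamline_voxels(points_mm: np.ndarray, voxel_size, shape) -> np.ndarray:
    """Unique linear voxel indices entered by one polyline.

    Voxel entry is decided from segment midpoints as well as vertices: FACT
    vertices sit exactly on voxel faces, so the midpoint of two consecutive
    boundary crossings identifies the transited voxel unambiguously; for
    sub-voxel steps (probabilistic tracking, step 0.1 mm < voxel 0.3 mm) the
    vertices themselves cover every entered voxel.
    """
    pts = np.asarray(points_mm, dtype=float)
    if len(pts) > 1:
        mids = 0.5 * (pts[1:] + pts[:-1])
        pts = np.vstack([pts, mids])
    h = np.asarray(voxel_size)
    idx = np.floor(pts / h).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    if not inside.any():
        return np.empty(0, dtype=np.int64)
    return np.unique(np.ravel_multi_index(idx[inside].T, shape))


def _visited_lists(streamlines: StreamlineSet):
    if streamlines.visited is not None:
        return streamlines.visited
    return [
        streamline_voxels(s, streamlines.voxel_size, streamlines.shape)
        for s in streamlines.streamlines
    ]


def streamline_interface_ddm(streamlines: StreamlineSet, interface: InterfaceSet) -> SurfaceDDM:
    """Distinct streamlines entering each interface voxel.

    A streamline crossing one interface voxel several times contributes one
    count there (the density is a per-streamline count, not a visit count).
    """
    counts = np.zeros(len(interface))
    if len(streamlines):
        from .tracking import visited_pairs

        imap = np.full(int(np.prod(interface.shape)), -1, dtype=np.int64)
        imap[interface.linear_indices()] = np.arange(len(interface))
        sid, vox = visited_pairs(streamlines)
        pos = imap[vox]
        on_if = pos >= 0
        counts = np.bincount(pos[on_if], minlength=len(interface)).astype(float)
    tag = "ds_stream" if streamlines.provenance == "DS" else "prob_stream"
    return SurfaceDDM(density=counts, interface=interface, provenance=tag)


def terminal_ddm(streamlines: StreamlineSet, roi_map: np.ndarray, interface: InterfaceSet) -> SurfaceDDM:
    """Streamline terminals in projection-region gray matter, counted at the
    nearest interface voxel.

    Terminals are the final vertices of both directed halves of each
    bidirectionally tracked streamline; terminals outside projection gray
    matter (e.g. in white matter) are not counted.
    """
    counts = np.zeros(len(interface))
    if len(streamlines):
        h = np.asarray(interface.voxel_size)
        pts = streamlines.terminals()
        idx = np.floor(pts / h).astype(int)
        shp = np.asarray(interface.shape)
        inside = np.all((idx >= 0) & (idx < shp), axis=1)
        idx, pts = idx[inside], pts[inside]
        in_roi = np.asarray(roi_map)[tuple(idx.T)] > 0
        pts = pts[in_roi]
        if len(pts):
            tree = cKDTree(interface.centres_mm())
            k = min(4, len(interface))
            dist, cand = tree.query(pts, k=k)
            dist = np.atleast_2d(dist.T).T
            cand = np.atleast_2d(cand.T).T
            tie = dist <= dist[:, :1] + 1e-9
            chosen = np.where(tie, cand, len(interface) + 1).min(axis=1)
            np.add.at(counts, chosen, 1.0)
    return SurfaceDDM(density=counts, interface=interface, provenance="ds_terminal")


def probabilistic_interface_ddm(visitation: np.ndarray, interface: InterfaceSet) -> SurfaceDDM:
    """Restriction of a visitation density to the interface voxels."""
    vis = np.asarray(visitation, dtype=float)
    if vis.shape != interface.shape:
        raise ValueError("visitation volume shape does not match the interface")
    density = vis[tuple(interface.voxels.T)]
    return SurfaceDDM(density=density, interface=interface, provenance="prob_stream")
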