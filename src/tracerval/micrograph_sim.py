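"""Synthetic light-micrograph generator with planted interface-crossing fibers.

Emulates tracer-labelled tissue micrographs: dark elongated fiber profiles on
a bright, unevenly illuminated background, a known white/gray-matter boundary
curve, plus round clutter objects that violate the fiber shape filters.  The
number of planted fibers intersecting the boundary band is the counting
ground truth for the segmentation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon, disk

from .histology import Micrograph

__all__ = ["MicrographTruth", "make_micrograph", "default_boundary_markers"]


@dataclass
class MicrographTruth:
    crossing_count: int
    boundary_markers: np.ndarray  # (n, 2) px, ordered along the boundary
    fiber_centroids: np.ndarray = field(default=None)  # crossing fibers only
    n_noncrossing: int = 0
    n_clutter: int = 0


def _boundary_y(x: np.ndarray, size: int, wave_amp: float, phase: float) -> np.ndarray:
    return size / 2 + wave_amp * np.sin(2 * np.pi * x / size + phase)


def default_boundary_markers(size: int, wave_amp: float, phase: float, n: int = 24) -> np.ndarray:
    x = np.linspace(0, size - 1, n)
    return np.column_stack([x, _boundary_y(x, size, wave_amp, phase)])


def _rect_mask(shape, centre, angle, length, width):
    """Pixel coordinates of a rotated rectangle (rows, cols)."""
    d = np.array([np.cos(angle), np.sin(angle)])
    p = np.array([-d[1], d[0]])
    c = np.asarray(centre, dtype=float)
    corners = np.array(
        [
            c + d * length / 2 + p * width / 2,
            c + d * length / 2 - p * width / 2,
            c - d * length / 2 - p * width / 2,
            c - d * length / 2 + p * width / 2,
        ]
    )
    return polygon(corners[:, 1], corners[:, 0], shape=shape)  # (row=y, col=x)


def make_micrograph(
    n_crossing: int = 20,
    n_noncrossing: int = 10,
    n_clutter: int = 8,
    size: int = 2048,
    resolution_um_per_px: float = 0.87,
    illumination_gradient: float = 0.15,
    noise: float = 0.04,
    rng_seed: int = 0,
    fiber_length_px: tuple = (115, 160),
    fiber_width_px: float = 3.0,
    clutter_radius_px: tuple = (6, 12),
    wave_amp_px: float = None,
    planted_fibers: list = None,
    boundary_margin_px: float = 14.0,
):
    """Generate a synthetic micrograph and its counting ground truth.

    Returns ``(Micrograph, MicrographTruth)``.  Crossing fibers are centred on
    the boundary curve and oriented near its local normal, so the planted
    crossing count is exact by construction; non-crossing fibers and clutter
    are kept clear of the boundary band.  ``planted_fibers`` may supply
    explicit ``(cx, cy, angle, length, crossing_flag)`` tuples instead of the
    random layout; objects outside the image raise an error.
    """
    rng = np.random.default_rng(rng_seed)
    shape = (size, size)
    if wave_amp_px is None:
        wave_amp_px = size / 14.0
    phase = rng.uniform(0, 2 * np.pi)
    markers = default_boundary_markers(size, wave_amp_px, phase)

    xs = np.arange(size, dtype=float)
    by = _boundary_y(xs, size, wave_amp_px, phase)
    # local normal angle of the boundary at integer x
    slope = np.gradient(by, xs)
    normal_angle = np.arctan2(1.0, -slope)  # perpendicular to the local tangent (1, slope)

    image = np.full(shape, 0.75, dtype=float)
    ramp = np.linspace(-0.5, 0.5, size)
    image += illumination_gradient * ramp[None, :]  # varies along x

    occupancy = np.zeros(shape, dtype=bool)
    pad = 4

    def try_place(mask_rc):
        rr, cc = mask_rc
        if len(rr) == 0:
            return False
        r0, r1 = max(rr.min() - pad - 1, 0), min(rr.max() + pad + 2, size)
        c0, c1 = max(cc.min() - pad - 1, 0), min(cc.max() + pad + 2, size)
        window = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        window[rr - r0, cc - c0] = True
        grown = ndimage.binary_dilation(window, iterations=pad)
        if np.any(grown & occupancy[r0:r1, c0:c1]):
            return False
        occupancy[r0:r1, c0:c1] |= grown
        return True

    crossing_centroids = []
    placed_cross = placed_non = placed_clutter = 0

    def plant_fiber(cx, cy, angle, length, crossing):
        nonlocal placed_cross, placed_non
        if not (0 <= cx < size and 0 <= cy < size):
            raise ValueError(f"planted object at ({cx:.0f}, {cy:.0f}) is outside the image")
        mask = _rect_mask(shape, (cx, cy), angle, length, fiber_width_px)
        if not try_place(mask):
            return False
        image[mask] -= 0.45
        if crossing:
            crossing_centroids.append((cx, cy))
            placed_cross += 1
        else:
            placed_non += 1
        return True

    if planted_fibers is not None:
        for cx, cy, angle, length, crossing in planted_fibers:
            if not plant_fiber(cx, cy, angle, length, bool(crossing)):
                raise ValueError("explicit planted fibers overlap; adjust layout")
    else:
        # stratified x slots along the boundary keep crossing fibers from
        # colliding, so the requested crossing count is planted exactly
        slots = np.linspace(0.06 * size, 0.94 * size, max(n_crossing, 1), endpoint=False)
        slot_w = (0.88 * size) / max(n_crossing, 1)
        for s in slots[:n_crossing]:
            for _ in range(40):
                cx = s + rng.uniform(0.15, 0.85) * slot_w
                cy = by[int(cx)] + rng.uniform(-6, 6)
                angle = normal_angle[int(cx)] + rng.uniform(-0.2, 0.2)
                length = rng.uniform(*fiber_length_px)
                if plant_fiber(cx, cy, angle, length, True):
                    break

        tries = 0
        while placed_non < n_noncrossing and tries < 100 * max(n_noncrossing, 1):
            tries += 1
            cx = rng.uniform(0.05 * size, 0.95 * size)
            cy = rng.uniform(0.05 * size, 0.95 * size)
            length = rng.uniform(*fiber_length_px)
            clearance = length / 2 + boundary_margin_px + 55  # stay clear of +-50 px shifts
            if abs(cy - by[int(cx)]) < clearance:
                continue
            plant_fiber(cx, cy, rng.uniform(0, np.pi), length, False)

        tries = 0
        while placed_clutter < n_clutter and tries < 100 * max(n_clutter, 1):
            tries += 1
            cx = rng.uniform(0.05 * size, 0.95 * size)
            cy = rng.uniform(0.05 * size, 0.95 * size)
            r = rng.uniform(*clutter_radius_px)
            if abs(cy - by[int(cx)]) < r + boundary_margin_px + 55:
                continue
            mask = disk((cy, cx), r, shape=shape)
            if try_place(mask):
                image[mask] -= 0.40
                placed_clutter += 1

    image = ndimage.gaussian_filter(image, 0.8)
    if noise > 0:
        image = image + rng.normal(0.0, noise, shape)
    image = np.clip(image, 0.0, 1.0)

    m = Micrograph(image=image, resolution=resolution_um_per_px, space_tag="high_res")
    truth = MicrographTruth(
        crossing_count=placed_cross,
        boundary_markers=markers,
        fiber_centroids=np.asarray(crossing_centroids, dtype=float).reshape(-1, 2),
        n_noncrossing=placed_non,
        n_clutter=placed_clutter,
    )
    return m, truth
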