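"""Diffusion acquisition scheme and tensor-based DWI signal simulation.

The emulated acquisition matches the validation study's protocol: one b = 0
image plus 31 diffusion-weighted directions at b = 1200 s/mm^2, 0.3 mm
isotropic voxels, magnitude (Rician) noise at SNR ~ 25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiffusionScheme", "DWIVolume", "make_scheme", "simulate_dwi"]

DEFAULT_B = 1200.0  # s/mm^2
DEFAULT_N_DIRECTIONS = 31


@dataclass(frozen=True)
class DiffusionScheme:
    """b-values (s/mm^2) and unit gradient directions, one row per acquisition."""

    b_values: np.ndarray
    gradient_directions: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float)
        g = np.asarray(self.gradient_directions, dtype=float)
        if b.ndim != 1 or g.shape != (b.size, 3):
            raise ValueError("b_values must be (n,) and gradient_directions (n, 3)")
        if not np.any(b == 0):
            raise ValueError("scheme needs at least one b = 0 acquisition")
        nz = b > 0
        norms = np.linalg.norm(g[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("nonzero-b gradient directions must be unit vectors")
        if self._rank(g[nz]) < 3 or nz.sum() < 6:
            raise ValueError("need >= 6 non-collinear nonzero-b directions")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "gradient_directions", g)

    @staticmethod
    def _rank(g: np.ndarray) -> int:
        return int(np.linalg.matrix_rank(g))

    def __len__(self) -> int:
        return self.b_values.size


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal (x, y, z, acquisition)."""

    signal: np.ndarray
    scheme: DiffusionScheme
    voxel_size: tuple

    def __post_init__(self):
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 4 or sig.shape[3] != len(self.scheme):
            raise ValueError("signal must be 4D with acquisition axis matching the scheme")
        if np.any(sig < 0):
            raise ValueError("signal must be nonnegative")
        self.signal = sig
        self.voxel_size = tuple(float(v) for v in self.voxel_size)


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on the upper hemisphere."""
    i = np.arange(n, dtype=float)
    golden = (1 + 5**0.5) / 2
    z = (i + 0.5) / n  # upper hemisphere only
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    g = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def make_scheme(n_directions: int = DEFAULT_N_DIRECTIONS, b_value: float = DEFAULT_B) -> DiffusionScheme:
    """One b = 0 acquisition plus ``n_directions`` directions at ``b_value``."""
    dirs = _fibonacci_hemisphere(n_directions)
    b = np.concatenate([[0.0], np.full(n_directions, float(b_value))])
    g = np.vstack([[0.0, 0.0, 0.0], dirs])
    return DiffusionScheme(b_values=b, gradient_directions=g)


def tensor_attenuation(tensors: np.ndarray, scheme: DiffusionScheme) -> np.ndarray:
    """exp(-b g^T D g) for a (..., 3, 3) tensor array; shape (..., n_acq)."""
    g = scheme.gradient_directions
    quad = np.einsum("ai,...ij,aj->...a", g, tensors, g)
    return np.exp(-scheme.b_values * quad)


def simulate_dwi(
    tensor_field,
    scheme: DiffusionScheme,
    s0: float = 1000.0,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> DWIVolume:
    """Simulate the magnitude DWI signal of a tensor field.

    Noiseless signal is ``s0 * exp(-b g^T D g)`` per voxel and acquisition;
    with ``noise_sigma > 0`` the signal is Rician:
    ``|s + n1 + i n2|`` with ``n1, n2 ~ N(0, noise_sigma^2)``.  ``s0`` may be a
    scalar or a per-voxel array (used to dim non-tissue background).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    tensors = np.asarray(tensor_field.tensor if hasattr(tensor_field, "tensor") else tensor_field)
    if tensors.shape[-2:] != (3, 3):
        raise ValueError("tensor field must have shape (..., 3, 3)")
    evals = np.linalg.eigvalsh(tensors)
    bad = np.min(evals, axis=-1) < -1e-12
    if np.any(bad):
        idx = tuple(int(c[0]) for c in np.nonzero(bad))
        raise ValueError(f"tensor at voxel {idx} is not positive semidefinite")
    s0_arr = np.asarray(s0, dtype=float)
    signal = s0_arr[..., None] * tensor_attenuation(tensors, scheme) if s0_arr.ndim else s0_arr * tensor_attenuation(tensors, scheme)
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        n1 = rng.normal(0.0, noise_sigma, signal.shape)
        n2 = rng.normal(0.0, noise_sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    voxel_size = getattr(tensor_field, "voxel_size", (1.0, 1.0, 1.0))
    return DWIVolume(signal=signal, scheme=scheme, voxel_size=voxel_size)
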