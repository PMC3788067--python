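import numpy as np
import pytest

from tracerval.dwi import make_scheme, simulate_dwi
from tracerval.phantom import PhantomConfig, make_phantom
from tracerval.tensors import fit_tensor
from tracerval.transfer import extract_interface


def small_phantom_config(**kw):
    """A compact slab phantom for unit tests (fits a 40x40x32 grid)."""
    defaults = dict(
        grid_shape=(40, 40, 32),
        gm_start=20,
        gm_thickness=4,
        injection_radius_mm=2.0,
        roi_ring_radius_mm=4.0,
        roi_radius_mm=0.9,
        descent_ring_radius_mm=1.3,
        max_bundle_radius_mm=0.6,
        n_projection_rois=6,
    )
    defaults.update(kw)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    cfg = small_phantom_config()
    tissue, tensors = make_phantom(cfg)
    return cfg, tissue, tensors


@pytest.fixture(scope="session")
def small_fitted(small_phantom):
    """Small phantom with noisy DWI simulation and tensor refit."""
    cfg, tissue, tensors_true = small_phantom
    scheme = make_scheme()
    s0 = np.where(tissue.label_volume != 0, 1000.0, 50.0)
    dwi = simulate_dwi(tensors_true, scheme, s0=s0,
                       noise_sigma=cfg.noise_sigma * 1000.0, rng_seed=11)
    tf = fit_tensor(dwi, mask=tissue.label_volume != 0)
    interface = extract_interface(tissue.label_volume, cfg.voxel_size)
    return cfg, tissue, tf, interface
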