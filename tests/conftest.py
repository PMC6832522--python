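import numpy as np
import pytest

from tregswitch import synthetic_data as sd
from tregswitch import treg_dynamics as td


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def model_iii_params():
    return td.ModelParams(k_f=0.2, k_r=0.05)


@pytest.fixture
def model_iii_dataset(model_iii_params):
    """Noise-free model-III observations on a 20-point grid."""
    return sd.generate_trajectories(
        td.ModelSpec("III_plasticity"),
        model_iii_params,
        x0=1000.0,
        y0=10.0,
        times=np.linspace(0.0, 48.0, 20),
        noise_sd=0.0,
    )


@pytest.fixture
def carpet_81():
    return sd.generate_spatial_image(
        sd.SpatialImageSpec(shape=(81, 81), pattern="sierpinski_carpet")
    )


def naive_box_masses(pixels: np.ndarray, eps: int) -> list[int]:
    """Brute-force per-box mass of the origin-anchored eps tiling."""
    h, w = pixels.shape
    masses = []
    for r0 in range(0, h, eps):
        for c0 in range(0, w, eps):
            masses.append(int(pixels[r0 : r0 + eps, c0 : c0 + eps].sum()))
    return masses
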