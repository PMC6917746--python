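import numpy as np
import pytest

from embryoflow import EmbryoSimConfig, SphericalFrame, simulate_embryo_tracks


@pytest.fixture(scope="session")
def frame():
    return SphericalFrame.canonical(350.0)


@pytest.fixture(scope="session")
def small_embryo():
    """A quiet little embryo shared by read-only tests."""
    cfg = EmbryoSimConfig(n_cells=80, t_end=8.0, seed=42, noise_sd=0.5)
    obs, truth = simulate_embryo_tracks(cfg)
    return cfg, obs, truth


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
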