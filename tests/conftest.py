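import numpy as np
import pytest

from ringhomog.phantom import PhantomSpec, generate_growth_ring_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default growth-ring phantom rendered without noise or inhomogeneity."""
    spec = PhantomSpec()
    vol, truth = generate_growth_ring_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom with Gaussian noise and strong multiplicative inhomogeneity."""
    spec = PhantomSpec(noise_sd=0.05, inhomogeneity_amplitude=0.6)
    vol, truth = generate_growth_ring_phantom(spec)
    return spec, vol, truth


def iso_stiffness(E: float, nu: float) -> np.ndarray:
    """Isotropic stiffness in engineering Voigt form (test oracle)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C
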