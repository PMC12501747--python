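import numpy as np
import pytest

from radish import AcquisitionContext, WasabiParams, ZSpectrum, wasabi_forward

#: 7 T proton reference frequency, MHz.
OMEGA0_7T = 42.577 * 7.0


@pytest.fixture(scope="session")
def ctx7t() -> AcquisitionContext:
    """7 T-like WASABI protocol: tp = 5 ms, nominal B1 = 3.7 uT."""
    return AcquisitionContext(omega0=OMEGA0_7T, tp=5e-3, b1_nominal=3.7)


@pytest.fixture(scope="session")
def offsets49() -> np.ndarray:
    return np.linspace(-1.5, 1.5, 49)


@pytest.fixture(scope="session")
def offsets25() -> np.ndarray:
    return np.linspace(-1.5, 1.5, 25)


def make_spectrum(
    ctx: AcquisitionContext,
    offsets: np.ndarray,
    delta_omega: float = 0.3,
    b1: float = 3.7,
    d: float = 1.0,
    c: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ZSpectrum:
    """Magnitude spectrum from the signed model, optionally with seeded
    Gaussian noise applied before magnitude detection."""
    theta = WasabiParams(c=c, d=d, delta_omega=delta_omega, b1=b1)
    values = wasabi_forward(offsets, theta, ctx)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, offsets.size)
    return ZSpectrum(offsets=offsets, values=np.abs(values))


@pytest.fixture(scope="session")
def fig1_spectrum(ctx7t, offsets49) -> ZSpectrum:
    """The worked-example spectrum: delta_omega = 0.3 ppm, B1 = 3.7 uT,
    c = d = 1, 49 offsets over -1.5..1.5 ppm, noiseless."""
    return make_spectrum(ctx7t, offsets49)
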