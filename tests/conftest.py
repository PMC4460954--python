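"""Shared fixtures: small synthetic datasets with known structure."""

import numpy as np
import pytest

import otochron as oc


@pytest.fixture(scope="session")
def default_signal():
    """Latent climate signal covering every year a default fish can live."""
    _, signal = oc.simulate_climate(range(1935, 2006), seed=7)
    return signal


@pytest.fixture(scope="session")
def default_fish(default_signal):
    """Default 36-fish, 3-transect collection (weak common signal)."""
    fish, truth = oc.simulate_fish(oc.SimulationConfig(seed=7), default_signal)
    return fish, truth


@pytest.fixture(scope="session")
def zero_noise_fish(default_signal):
    """Deterministic collection: widths are exactly the growth curve."""
    cfg = oc.SimulationConfig(
        seed=7,
        signal_effect=0.0,
        individual_sd=0.0,
        measurement_sd=0.0,
        fish_effect_sd=0.0,
    )
    fish, truth = oc.simulate_fish(cfg, default_signal)
    return fish, truth


def series_with_correlation(base: np.ndarray, r: float, rng) -> np.ndarray:
    """A vector with exact sample correlation ``r`` against ``base``."""
    z1 = (base - base.mean()) / np.linalg.norm(base - base.mean())
    noise = rng.normal(size=base.size)
    noise = noise - noise.mean()
    noise = noise - (noise @ z1) * z1
    z2 = noise / np.linalg.norm(noise)
    v = r * z1 + np.sqrt(1.0 - r**2) * z2
    return 1.0 + 0.1 * v / np.abs(v).max()  # positive, mean ~1
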