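import numpy as np
import pytest

from spastocsy import (MultipletSpec, SimulationConfig, SpectrumSet,
                       build_reference_spectra, simulate_spectra)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_spectra():
    """4 samples x 12 points, deterministic, with a clear two-peak shape."""
    g = np.random.default_rng(7)
    ppm = np.linspace(1.0, 1.11, 12)
    base = np.array([0, 1, 4, 9, 4, 1, 0, 2, 6, 2, 0, 0], dtype=float)
    scale = np.array([1.0, 1.5, 2.0, 0.7])
    X = scale[:, None] * base[None, :] + 0.01 * g.normal(size=(4, 12))
    return SpectrumSet(ppm, X)


@pytest.fixture(scope="session")
def small_simulation():
    """One small simulated dataset (L=5, n=20) shared across tests."""
    cfg = SimulationConfig(L=5, n=20, p=1500, ppm_max=2.0, seed=42)
    rng = np.random.default_rng(42)
    ref = build_reference_spectra(cfg, MultipletSpec(), rng)
    observed, signal, conc = simulate_spectra(cfg, ref, rng)
    return cfg, ref, observed, signal, conc
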