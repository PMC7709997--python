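import numpy as np
import pytest

from resistkit.simulate import (
    DoseResponseSimConfig,
    FretSimConfig,
    ScreenSimConfig,
    simulate_dose_response,
    simulate_fret_movie,
    simulate_screen,
)


@pytest.fixture(scope="session")
def small_screen():
    """A 300-gene screen with 8 planted sensitizers and 8 resistors."""
    cfg = ScreenSimConfig(
        n_genes=300, n_sensitizers=8, n_resistors=8, plate_size=96, seed=42
    )
    design, wells, truth = simulate_screen(cfg)
    return cfg, design, wells, truth


@pytest.fixture(scope="session")
def dose_panel():
    """A 10-drug triplicate dilution panel with known IC50s."""
    cfg = DoseResponseSimConfig(n_drugs=10, seed=7)
    table, truth = simulate_dose_response(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def clean_fret_movie():
    """Noise-free 10-cell movie: segmentation and ratios are exact."""
    cfg = FretSimConfig(n_cells=10, intensity_noise_sd=0.0, seed=5)
    pair, traces, truth = simulate_fret_movie(cfg)
    return cfg, pair, traces, truth


@pytest.fixture(scope="session")
def noisy_fret_movie():
    cfg = FretSimConfig(n_cells=10, intensity_noise_sd=2.0, seed=9)
    pair, traces, truth = simulate_fret_movie(cfg)
    return cfg, pair, traces, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
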