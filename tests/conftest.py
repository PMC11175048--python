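import numpy as np
import pytest

from moistspec import SyntheticConfig, generate_dataset, preprocess_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_config():
    """Noise-free, scatter-free generator: spectra are deterministic
    functions of chemistry and the moist-dry difference is exactly rank 1."""
    cfg = SyntheticConfig(n_samples=15, seed=7, outlier_rate=0.0)
    cfg.scatter_sd_by_state = {k: 0.0 for k in cfg.scatter_sd_by_state}
    cfg.baseline_offset_sd = 0.0
    cfg.noise_sd = 0.0
    return cfg


@pytest.fixture
def small_config():
    """Small but fully featured generator configuration."""
    return SyntheticConfig(n_samples=20, seed=11)


@pytest.fixture(scope="session")
def small_processed():
    """Processed spectra for a 30-sample full-range campaign, shared across
    tests that only read it."""
    cfg = SyntheticConfig(n_samples=30, seed=21)
    raw, chem = generate_dataset(cfg, "full_range")
    processed = {}
    for treatment in ("field_moist", "lab_sieved", "lab_fine"):
        spectra, _ = preprocess_pipeline(raw.select(treatment=treatment))
        processed[treatment] = spectra
    return processed, chem
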