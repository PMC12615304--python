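"""Shared fixtures: one simulated study per noise regime, run once per session."""

import numpy as np
import pytest

from protegap import SyntheticConfig, run_pipeline, simulate


@pytest.fixture(scope="session")
def noise_free_study():
    """Default-scale simulation with all noise sources off.

    Used by the round-trip, novel-gene and gene-model-audit tests: with no
    noise peaks, no mass error, no PTMs and no noise-only spectra, every
    accepted PSM should be a true identification.
    """
    cfg = SyntheticConfig(seed=7, noise_peaks=0, mass_error_ppm=0.0,
                          ptm_rates={}, n_noise_spectra=0)
    study = simulate(cfg)
    result = run_pipeline(study)
    return study, result


@pytest.fixture(scope="session")
def ptm_study():
    """Default-noise simulation with planted PTMs, for annotator validation."""
    cfg = SyntheticConfig(seed=11, peptide_sampling_depth=150, n_noise_spectra=200)
    study = simulate(cfg)
    result = run_pipeline(study)
    return study, result


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
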