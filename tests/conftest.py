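import warnings

import numpy as np
import pytest

from expomix import (MixtureSimConfig, generate_exposure_matrix,
                     generate_outcomes, scale_columns, substitute_lod)

warnings.filterwarnings("ignore", category=RuntimeWarning, message=".*did not converge.*")


@pytest.fixture(scope="session")
def clean_study():
    """Noiseless, uncensored block-structured study (exact-recovery regime)."""
    cfg = MixtureSimConfig(n_participants=200, n_analytes=30, true_rank=3,
                           spike_fraction=0.02, lod_quantiles=0.0, noise_sd=0.0, seed=11)
    return generate_exposure_matrix(cfg)


@pytest.fixture(scope="session")
def censored_study():
    """Same regime with 30% left-censoring per analyte."""
    cfg = MixtureSimConfig(n_participants=200, n_analytes=30, true_rank=3,
                           spike_fraction=0.02, lod_quantiles=0.3, noise_sd=0.0, seed=11)
    return generate_exposure_matrix(cfg)


@pytest.fixture(scope="session")
def outcome_study():
    """Study with liver outcomes attached (sigmoidal h on exposures 0 and 5)."""
    cfg = MixtureSimConfig(n_participants=300, n_analytes=10, true_rank=3,
                           spike_fraction=0.02, lod_quantiles=0.0, noise_sd=1.0,
                           h_form="sigmoidal", active_exposures=(0, 5), seed=11)
    return generate_outcomes(generate_exposure_matrix(cfg), cfg)


@pytest.fixture()
def scaled_clean(clean_study):
    pan = substitute_lod(clean_study.panel)
    scaled, factors, lod_scaled = scale_columns(pan)
    return pan, scaled, factors, lod_scaled
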