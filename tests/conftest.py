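import dataclasses

import numpy as np
import pytest

from spermraman.synthetic_data import GeneratorConfig, PeakSpec, calibrate_defaults


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return calibrate_defaults()


@pytest.fixture()
def small_clean_config(default_config) -> GeneratorConfig:
    """Tiny noiseless cohort on a short grid for exactness tests."""
    return dataclasses.replace(
        default_config,
        n_x=3, n_y=2, n_scans=3, noise_sd=0.0, cell_cv=0.0, seed=7,
    )


@pytest.fixture()
def fast_config(default_config) -> GeneratorConfig:
    """Small noisy cohort, full grid, cheap enough for per-test use."""
    return dataclasses.replace(
        default_config, n_x=8, n_y=6, n_scans=5, seed=11,
    )


@pytest.fixture()
def single_peak_config() -> GeneratorConfig:
    """One Gaussian DNA peak at 785 on a zero baseline, no noise."""
    return GeneratorConfig(
        n_x=1, n_y=1,
        grid=(600.0, 1300.0, 1.0),
        n_scans=1,
        peaks=(PeakSpec(785.0, 14.0, 1000.0, dna_linked=True),),
        baseline=(0.0,),
        noise_sd=0.0,
        cell_cv=0.0,
        dna_scale_x=1.5,
        dna_scale_y=1.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
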