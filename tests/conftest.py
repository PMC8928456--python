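import dataclasses

import pytest

from ornrbe import BootstrapSpec, PipelineConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """Shared 300-patient cohort (records, samples) for unit tests."""
    return generate_cohort(
        default_config.covariates,
        default_config.confounding,
        default_config.dose_field,
        default_config.outcome,
        300,
        seed=11,
    )


@pytest.fixture(scope="session")
def full_cohort(default_config):
    """Full-size cohort matching the analysis scale."""
    return generate_cohort(
        default_config.covariates,
        default_config.confounding,
        default_config.dose_field,
        default_config.outcome,
        1266,
        seed=7,
    )


@pytest.fixture()
def fast_bootstrap() -> BootstrapSpec:
    return BootstrapSpec(n_reps=100, seed=5)


@pytest.fixture()
def fixture_config(default_config) -> PipelineConfig:
    """Small, fast pipeline configuration for end-to-end tests."""
    return dataclasses.replace(
        default_config,
        n_patients=400,
        seed=23,
        bootstrap=BootstrapSpec(n_reps=50, seed=23),
    )
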