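import time

import pytest

from spcpanel.config import GeneratorConfig, PipelineConfig
from spcpanel.pipeline import roundtrip_quantify
from spcpanel.synthetic import generate_cohort

ACCEPTANCE_SEED = 1


@pytest.fixture(scope="session")
def population_run():
    """Full-population cohort (n=4025) through the complete spectral round
    trip at the default calibration; returns (quantified frame, elapsed s)."""
    cfg = PipelineConfig(
        generator=GeneratorConfig.population_default(seed=ACCEPTANCE_SEED),
        seed=ACCEPTANCE_SEED,
    )
    t0 = time.time()
    cohort = generate_cohort(cfg.generator)
    quantified = roundtrip_quantify(cohort, cfg)
    return quantified, time.time() - t0


@pytest.fixture(scope="session")
def healthy_run():
    """Healthy-reference cohort (n=4000) through the spectral round trip."""
    cfg = PipelineConfig(
        generator=GeneratorConfig.healthy_default(seed=ACCEPTANCE_SEED),
        seed=ACCEPTANCE_SEED,
    )
    t0 = time.time()
    cohort = generate_cohort(cfg.generator)
    quantified = roundtrip_quantify(cohort, cfg)
    return quantified, time.time() - t0


@pytest.fixture()
def small_config():
    """Tiny cohort config for fast pipeline tests."""
    return PipelineConfig(
        generator=GeneratorConfig(
            n_participants=3,
            timepoints_per_participant=1,
            n_missing_followup=0,
            n_basque=0,
            seed=11,
        ),
        seed=11,
    )
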