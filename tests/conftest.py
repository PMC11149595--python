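import numpy as np
import pytest

import lutadose as ld


@pytest.fixture(scope="session")
def default_config():
    return ld.CohortConfig()


@pytest.fixture(scope="session")
def noisy_cohort(default_config):
    """One seeded 35-patient cohort with Poisson counting noise."""
    return ld.generate_cohort(default_config, seed=11)


@pytest.fixture(scope="session")
def noise_free_cohort():
    from dataclasses import replace

    cfg = replace(ld.CohortConfig(), noise_free=True)
    return cfg, ld.generate_cohort(cfg, seed=12)


@pytest.fixture(scope="session")
def engine_result(default_config, noisy_cohort):
    return ld.process_cohort(
        noisy_cohort.timepoints,
        ld.CalibrationFactor(default_config.calibration_cps_per_mbq),
        default_config.rc_curve,
        ld.EngineConfig(),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
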