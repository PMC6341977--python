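import numpy as np
import pytest

import divekit as dk


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture(scope="session")
def small_juvenile_cohort():
    """Four juveniles, 40-day trips: cheap but exercises the full chain."""
    params = dk.juvenile_defaults(n_individuals=4, trip_days_max=40.0, seed=11)
    return params, dk.simulate_cohort(params)


@pytest.fixture(scope="session")
def default_report():
    """The end-to-end default run (20 juveniles + 9 adults, seed 1)."""
    from divekit.params import PipelineConfig
    from divekit.pipeline import run_pipeline

    return run_pipeline(PipelineConfig(seed=1))
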