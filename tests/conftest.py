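import numpy as np
import pytest

from violacap import GeneratorParams, SimConfig, generate_field_dataset, presets, run_simulation


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reported_fits():
    """The fitted families reported for the 2013 survey."""
    return {
        "density": presets.density_mixture(),
        "leaves": presets.leaves_fit(),
        "leafarea": presets.leafarea_fit(),
        "consumption": presets.consumption_fit(),
    }


@pytest.fixture(scope="session")
def headline_sample(reported_fits):
    """The full 10,000-iteration capacity run at the total study area."""
    config = SimConfig(reference_area_m2=presets.TOTAL_AREA_M2, seed=1)
    return run_simulation(
        config,
        reported_fits["density"],
        reported_fits["leaves"],
        reported_fits["leafarea"],
        reported_fits["consumption"],
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic field season at the survey's sample sizes."""
    params = GeneratorParams(seed=7)
    return generate_field_dataset(params)
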