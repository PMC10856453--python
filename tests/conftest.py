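import warnings

import pytest

from pfascreen.pipeline import PipelineConfig, run_pipeline
from pfascreen.simulate import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def default_scenario():
    """The default synthetic roe-deer scenario at a fixed seed."""
    return generate_scenario(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(default_scenario):
    sc = default_scenario
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(
            sc.features, sc.samples, sc.suspects, sc.spectra, sc.library,
            PipelineConfig(),
        )
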