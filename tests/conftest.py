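import pytest

from phytonet import pipeline as pl
from phytonet.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset, fixed seed, shared across the suite."""
    return generate_dataset(GeneratorConfig(rng_seed=0))


@pytest.fixture(scope="session")
def pipeline_result():
    """One full pipeline run on the default synthetic dataset."""
    return pl.run(pl.PipelineConfig(rng_seed=0))
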