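import pytest
from hypothesis import HealthCheck, settings

import coexscreen as cx

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def design() -> cx.DesignSpec:
    return cx.default_design()


@pytest.fixture(scope="session")
def paper_cfg() -> cx.GeneratorConfig:
    return cx.paper_like_config(seed=11)


@pytest.fixture(scope="session")
def paper_table(paper_cfg) -> cx.MeasurementTable:
    return cx.generate_dataset(paper_cfg)


@pytest.fixture(scope="session")
def noise_free_cfg(design) -> cx.GeneratorConfig:
    return cx.build_generator_config(design=design, noise_sd_log2=0.0, seed=5)
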