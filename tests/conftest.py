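import pytest

from phifilter.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def default_cfg() -> PipelineConfig:
    """Shipped default pipeline configuration (lexicons built once)."""
    return PipelineConfig.default()
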