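import pytest

from nocidet import LumpedParams, ModelConfig, StimulusTrain


@pytest.fixture(scope="session")
def ref_params() -> LumpedParams:
    return LumpedParams.reference()


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def single_p21() -> StimulusTrain:
    return StimulusTrain(nop=1, pw=0.21)


@pytest.fixture(scope="session")
def double20() -> StimulusTrain:
    return StimulusTrain(nop=2, ipi=20.0, pw=0.525)


@pytest.fixture(scope="session")
def double50() -> StimulusTrain:
    return StimulusTrain(nop=2, ipi=50.0, pw=0.525)
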