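import pytest

from sdturnover.model import ModelConfig, MutationRates, SelectionParams

MUT = MutationRates(1e-6, 1e-6)

# canonical fitness schemes for the four modes of selection
BALANCING = SelectionParams(s_m=0.02, s_f=-0.02, h_m=1.0, h_f=0.0)
NEGATIVE = SelectionParams(s_m=0.02, s_f=-0.04, h_m=0.5, h_f=0.5)
POSITIVE = SelectionParams(s_m=0.02, s_f=-0.01, h_m=0.5, h_f=0.5)
EQUALIZING = SelectionParams(s_m=0.02, s_f=-0.02, h_m=0.5, h_f=0.5)
NEUTRAL = SelectionParams(s_m=0.0, s_f=0.0, h_m=0.5, h_f=0.5)


def make_config(sel, N=10_000, r=0.0, case=1, mut=MUT) -> ModelConfig:
    return ModelConfig(N=N, r=r, case=case, selection=sel, mutation=mut)


@pytest.fixture
def balancing_cfg():
    return make_config(BALANCING)


@pytest.fixture
def negative_cfg():
    return make_config(NEGATIVE)


@pytest.fixture
def equalizing_cfg():
    return make_config(EQUALIZING)
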