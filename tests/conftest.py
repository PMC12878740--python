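import pytest

from mgpbpk import ImplantConfig, PhysiologyParams, scale_implants


@pytest.fixture
def params() -> PhysiologyParams:
    """Healthy-adult reference physiology."""
    return PhysiologyParams()


@pytest.fixture
def screw(params) -> ImplantConfig:
    """A single 3.2 x 32 mm screw (sigma = 0.05 mmol/day)."""
    return scale_implants(0.05, 0.00527, 1, params)


@pytest.fixture
def inert_implant(params) -> ImplantConfig:
    """An implant zone with zero release (the sigma = 0 system)."""
    return ImplantConfig.from_totals(sigma=0.0, VI=0.00527, params=params)
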