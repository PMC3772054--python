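import pytest

from il15sim import (
    Dose,
    GeometryConstants,
    HighAffinityParams,
    IntermediateParams,
    steady_state_high_affinity,
    steady_state_intermediate,
)

#: serial doubling from 3.9 ng/ml plus the 2000 ng/ml saturating dose
DOSE_GRID = [3.9 * 2 ** i for i in range(9)] + [2000.0]

#: doses used in the proliferation experiments
ASSAY_DOSES = [9.0, 25.0, 50.0, 75.0]


@pytest.fixture(scope="session")
def geometry():
    return GeometryConstants()


@pytest.fixture(scope="session")
def params():
    return IntermediateParams()


@pytest.fixture(scope="session")
def ha_params():
    return HighAffinityParams()


@pytest.fixture(scope="session")
def intermediate_ss(params, geometry):
    """Algebraic intermediate-model steady states over the full dose grid."""
    return {d: steady_state_intermediate(Dose(d), params, geometry)
            for d in DOSE_GRID + ASSAY_DOSES}


@pytest.fixture(scope="session")
def high_affinity_ss(ha_params, geometry):
    """High-affinity steady states at the assay doses plus saturation."""
    return {d: steady_state_high_affinity(Dose(d), ha_params, geometry)
            for d in ASSAY_DOSES + [3.9, 2000.0]}
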