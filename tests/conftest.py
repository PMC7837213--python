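import numpy as np
import pytest

from aggrekin import (
    Condition,
    KineticParameters,
    NormalizedTrace,
    ScreenDesign,
    default_reference_parameters,
)


@pytest.fixture(scope="session")
def reference_params() -> KineticParameters:
    return default_reference_parameters()


@pytest.fixture(scope="session")
def two_hour_grid() -> np.ndarray:
    return np.arange(0.0, 7200.0, 120.0)


def model_trace(params: KineticParameters, t: np.ndarray, **cond) -> NormalizedTrace:
    """Noise-free normalized trace equal to the analytic model curve."""
    from aggrekin import fibril_mass_analytic

    curve = fibril_mass_analytic(t, params)
    condition = Condition(m0=params.m0, **cond)
    return NormalizedTrace(
        t=t, y=curve.M_norm, baseline=0.0, plateau=1.0, condition=condition
    )


@pytest.fixture(scope="session")
def screen_design() -> ScreenDesign:
    return ScreenDesign(rng_seed=0)
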