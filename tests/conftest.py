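import numpy as np
import pytest

from acidnit import (
    ChemKineticsParams,
    GasTransferParams,
    OperationTimeline,
    ScenarioConfig,
    generate_timeline,
)


@pytest.fixture
def mild_params():
    """Rate constants scaled down to a non-stiff regime for oracle checks."""
    return ChemKineticsParams(
        k2_fwd=2e4, k2_rev=1e5, k3=1e8, k4_fwd=1e6, k4_rev=10.0, k_n2o3=1e6, K_nh3_branch=10.0
    )


@pytest.fixture
def no_gas():
    return GasTransferParams(kLa_NO=0.0, kLa_NO2=0.0)


@pytest.fixture
def short_timeline():
    """Two-day synthetic operation at coarse resolution."""
    return generate_timeline(ScenarioConfig(duration=2.0, dt=0.02, seed=11))


def constant_timeline(
    duration=2.0, dt=0.01, Q=6.0, TAN_in=2000.0, pH=5.0, DO=5.0, T=25.0, EC=20.0,
    volume=12.0, f_ox=0.5,
):
    """Flat-driver timeline for analytic comparisons."""
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    ones = np.ones(n)
    return OperationTimeline(
        time=t, Q=Q * ones, TAN_in=TAN_in * ones, pH=pH * ones, DO=DO * ones,
        temperature=T * ones, conductivity=EC * ones, volume=volume, f_ox=f_ox,
    )
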