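import numpy as np
import pytest

from spikefit.model import SpikeParams
from spikefit.scantime import ScanConfig, ScanMode


@pytest.fixture
def example_params() -> SpikeParams:
    return SpikeParams(t0=4.0, FM=1.0, alpha=0.5, tauA=5.0, tauT=10.0)


@pytest.fixture
def uni_1000() -> ScanConfig:
    return ScanConfig.from_preset(1000, mode=ScanMode.UNIDIRECTIONAL)


@pytest.fixture
def bi_1000() -> ScanConfig:
    return ScanConfig.from_preset(1000, mode=ScanMode.BIDIRECTIONAL)


def random_valid_params(rng: np.random.RandomState, n: int,
                        tau_floor: float = 0.2,
                        alpha_max: float = 0.95) -> list[SpikeParams]:
    """Random draws over the model's validity region.

    ``alpha_max`` can be lowered to stay within the well-identified,
    spike-like part of parameter space (large build-up fractions make the
    FM/alpha/tauT trade-off nearly degenerate).
    """
    out = []
    while len(out) < n:
        p = SpikeParams(
            t0=rng.uniform(0.5, 60.0),
            FM=rng.uniform(0.05, 5.0),
            alpha=rng.uniform(0.0, alpha_max),
            tauA=rng.uniform(tau_floor, 15.0),
            tauT=rng.uniform(tau_floor, 25.0),
        )
        out.append(p)
    return out
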