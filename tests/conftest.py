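import numpy as np
import pytest

from doxypk import (
    AbsorptionParams,
    DispositionParams,
    DoseEvent,
    Route,
    published_model,
)

# Typical disposition parameter sets at three body weights (covariate-scaled
# values of the final model's bootstrap estimates).
DISP_10 = dict(cl=0.161, cl2=1.692, cl3=0.178, vc=0.192, v2=0.595, v3=0.295)
DISP_50 = dict(cl=0.259, cl2=1.179, cl3=0.072, vc=0.192, v2=0.595, v3=0.536)
DISP_100 = dict(cl=0.320, cl2=1.010, cl3=0.050, vc=0.192, v2=0.595, v3=0.699)


@pytest.fixture(scope="session")
def disp_50():
    return DispositionParams(**DISP_50)


@pytest.fixture(scope="session")
def disp_10():
    return DispositionParams(**DISP_10)


@pytest.fixture(scope="session")
def disp_100():
    return DispositionParams(**DISP_100)


@pytest.fixture(scope="session")
def feed_tls_abs():
    return AbsorptionParams(route=Route.FEED_TLS, ka=0.072, f=0.501)


@pytest.fixture(scope="session")
def iv_abs():
    return AbsorptionParams(route=Route.IV)


@pytest.fixture(scope="session")
def final_model():
    return published_model()


def random_disposition(rng: np.random.Generator) -> DispositionParams:
    """Random positive parameter set around the plausible range."""
    base = np.array([0.25, 1.0, 0.08, 0.2, 0.6, 0.5])
    values = base * np.exp(rng.uniform(-1.2, 1.2, size=6))
    return DispositionParams(
        cl=values[0], cl2=values[1], cl3=values[2], vc=values[3], v2=values[4], v3=values[5]
    )


def iv_bolus(amount: float = 8.68) -> list[DoseEvent]:
    return [DoseEvent(time=0.0, amount=amount, route=Route.IV)]
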