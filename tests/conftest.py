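import numpy as np
import pytest

from bpmpk.pkmodel import CovariateRecord, StructuralParams
from bpmpk.population import final_model


@pytest.fixture(scope="session")
def final():
    return final_model()


@pytest.fixture(scope="session")
def typical_patient(final):
    """Typical structural parameters at the reference covariates."""
    return final.typical(CovariateRecord(clcr=78.2, bun=6.8))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230915)


def random_params(rng, n):
    """Random positive two-compartment parameter sets, well separated phases."""
    out = []
    for _ in range(n):
        out.append(
            StructuralParams(
                cl=float(rng.uniform(1.0, 20.0)),
                v1=float(rng.uniform(5.0, 40.0)),
                q=float(rng.uniform(0.5, 15.0)),
                v2=float(rng.uniform(20.0, 150.0)),
            )
        )
    return out
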