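import numpy as np
import pytest

from tractoflux.mcm import FitConfig, McmFit, ZeppelinCompartment
from tractoflux.synthetic import gen_scheme


@pytest.fixture(scope="session")
def scheme():
    """Default 61-entry CUSP-like gradient table."""
    return gen_scheme(seed=1)


@pytest.fixture(scope="session")
def single_zeppelin_fit():
    """Canonical white-matter voxel: 20% free water + one zeppelin."""
    return McmFit(
        fw_weight=0.2,
        compartments=(
            ZeppelinCompartment(weight=0.8, axis=np.array([0.6, 0.48, 0.64]),
                                lambda_par=1.7e-3, lambda_perp=0.3e-3),
        ),
    )


@pytest.fixture
def fast_fit_config():
    return FitConfig(seed=0, n_starts=3)


def make_zeppelin(weight, axis, lpar=1.7e-3, lperp=0.3e-3):
    return ZeppelinCompartment(weight=weight, axis=np.asarray(axis, dtype=float),
                               lambda_par=lpar, lambda_perp=lperp)
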