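import numpy as np
import pytest

from cagetime import build_model_set, calibrate_offsets

#: the densely-early-sampled grid used by most fixtures (minutes)
GRID = np.array([0.0, 15, 30, 45, 60, 80, 100, 120, 160, 200, 240, 300])


@pytest.fixture(scope="session")
def times12():
    return GRID.copy()


@pytest.fixture(scope="session")
def models300():
    return build_model_set(300.0)


@pytest.fixture(scope="session")
def offsets200(models300, times12):
    """Complexity offsets from a scaled calibration run (shared across tests).

    n_per_model=200 at calibration noise 0.3 — the same offsets the
    model-recovery checks use, so they are computed once per session.
    """
    return calibrate_offsets(models300, times12, n_per_model=200, noise=0.3,
                             n_live=100, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
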