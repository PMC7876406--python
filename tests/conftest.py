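import numpy as np
import pytest

from stepnet import synth
from stepnet.containers import EpochedEEG
from stepnet.montage import grid_montage, standard_montage


@pytest.fixture(scope="session")
def montage64():
    return standard_montage()


@pytest.fixture(scope="session")
def montage16():
    """Small synthetic grid geometry for fast tests."""
    return grid_montage(4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_epochs(
    data: np.ndarray,
    montage,
    sfreq: float = 250.0,
    tmin_ms: float = -200.0,
    conditions=None,
) -> EpochedEEG:
    n = data.shape[0]
    conditions = (
        np.asarray(conditions) if conditions is not None else np.array(["A"] * n)
    )
    return EpochedEEG(
        data=data, sfreq=sfreq, tmin_ms=tmin_ms, montage=montage,
        conditions=conditions,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 subjects × 1 visit, short AOB: the miniature fixture for fast
    end-to-end tests."""
    cfg = synth.CohortConfig(
        n_healthy=2,
        n_patient=2,
        visits=1,
        seed=42,
        tasks=(synth.aob_task(60), synth.gng_task(40)),
    )
    return synth.Cohort(cfg)
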