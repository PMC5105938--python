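import numpy as np
import pytest

from osaprog.hrv_features import extract_feature_series
from osaprog.synthetic_data import SimulationConfig, generate_rr_series


@pytest.fixture(scope="session")
def series60():
    """A 60-minute synthetic annotated RR series (fixed seed)."""
    return generate_rr_series(SimulationConfig(duration_min=60, seed=1))


@pytest.fixture(scope="session")
def features60(series60):
    """Per-minute NPSD/LVM features of the 60-minute series."""
    return extract_feature_series(series60)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
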