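import numpy as np
import pytest

from aircast.pipeline import SplitSpec
from aircast.synthetic import PanelSpec, generate_panel, generate_tone_signal


@pytest.fixture(scope="session")
def panel6y():
    """Default six-year synthetic panel (2016-01-01 .. 2021-12-31)."""
    return generate_panel(PanelSpec(seed=42))


@pytest.fixture(scope="session")
def small_panel():
    """Three-year panel (2016-2018) for fast pipeline tests."""
    return generate_panel(PanelSpec(n_days=1096, seed=7))


@pytest.fixture(scope="session")
def small_split():
    return SplitSpec(train_years=(2016, 2017), test_years=(2018,))


@pytest.fixture(scope="session")
def two_tone():
    """Noiseless two-tone fixture with frequency ratio 10."""
    return generate_tone_signal([0.005, 0.05], [1.0, 1.0], 2000, 0.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
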