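import numpy as np
import pytest

from pmpanel import SyntheticConfig, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """Default-mechanism panel at desk scale (60 ZIPs x 17 years)."""
    cfg = SyntheticConfig(seed=42, n_zips=60)
    panel, truth = generate_panel(cfg)
    return panel, truth


@pytest.fixture(scope="session")
def tiny_config():
    """A 3-year, single-period configuration for fast structural tests."""
    return SyntheticConfig(
        seed=7,
        n_zips=50,
        year_start=2000,
        year_end=2002,
        periods=((2000, 2002),),
        period_trends=np.ones((1, 5)),
    )
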