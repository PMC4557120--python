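import numpy as np
import pytest

from photokin import SpectroTemporalMatrix


@pytest.fixture
def small_matrix():
    """3x4 toy difference matrix with ps times."""
    return SpectroTemporalMatrix(
        values=np.arange(12, dtype=float).reshape(3, 4) / 10.0,
        time_axis=np.array([1e-12, 2e-12, 3e-12]),
        wavelength_axis=np.array([400.0, 450.0, 500.0, 550.0]),
        window="fs_ns",
        kind="difference",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20150812)
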