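import numpy as np
import pytest

from irspec_calib import BandSpec, SpectraMatrix, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3 samples x 5 wavenumbers, descending axis."""
    return SpectraMatrix(
        intensities=np.array(
            [
                [0.11, 0.22, 0.31, 0.18, 0.07],
                [0.09, 0.25, 0.35, 0.20, 0.05],
                [0.15, 0.19, 0.28, 0.17, 0.09],
            ]
        ),
        wavenumbers=np.array([2000.0, 1600.0, 1200.0, 800.0, 400.0]),
        sample_ids=["a", "b", "c"],
    )


def tiny_config(seed=0, **overrides):
    """Fast synthetic config: 60 samples, 251 channels, same band layout."""
    defaults = dict(
        n_samples=60,
        wavenumber_grid=(1800.0, 800.0, 4.0),
        background_bands=[BandSpec(1640.0, 60.0, 1.5), BandSpec(900.0, 150.0, 1.0)],
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture
def tiny_cfg():
    return tiny_config()
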