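import numpy as np
import pytest

import qmapkit as qk


@pytest.fixture(scope="session")
def timing():
    return qk.SequenceTiming()


@pytest.fixture(scope="session")
def default_dictionary(timing):
    """Full default-grid dictionary (built once; several suites share it)."""
    return qk.build_dictionary(qk.DEFAULT_T1_GRID, qk.DEFAULT_T2_GRID, timing)


@pytest.fixture(scope="session")
def coarse_dictionary(timing):
    """Small dictionary for oracle comparisons and quick fits."""
    return qk.build_dictionary(
        np.arange(200.0, 1800.0, 50.0), np.arange(20.0, 500.0, 20.0), timing
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_layout():
    """Reduced phantom volume for fast segmentation/round-trip tests."""
    return qk.PhantomLayout(volume_shape=(64, 64, 64), voxel_size=(2.0, 2.0, 2.0),
                            vial_radius=7.0)
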