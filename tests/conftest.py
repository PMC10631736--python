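import numpy as np
import pytest

from patterncells.stimuli import DisplayGeometry


@pytest.fixture(scope="session")
def geometry():
    """Reduced-resolution analysis geometry used across tests."""
    return DisplayGeometry(pixels_x=48, pixels_y=36)


@pytest.fixture(scope="session")
def tiny_session():
    """Small but complete synthetic recording shared by session-level tests.

    Full 2 SF x 2 TF x 12 direction battery, reduced trial count and a short
    noise block to keep the suite fast.
    """
    from patterncells.units import make_session

    return make_session(
        population_config={
            "n_component": 2,
            "n_blobby": 1,
            "n_pattern": 1,
            "n_complex": 1,
        },
        protocol_config={
            "n_trials": 8,
            "noise": {"n_movies": 2, "duration": 15.0},
        },
        seed=101,
        geometry=DisplayGeometry(pixels_x=48, pixels_y=36),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
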