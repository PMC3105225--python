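import numpy as np
import pytest

from meanet.model import MEALayout, Recording, SpikeTrain, standard_layout


@pytest.fixture(scope="session")
def quad_layout() -> MEALayout:
    """Four electrodes on a 2x2 grid (corners kept)."""
    return standard_layout(2, 2, drop_corners=False)


@pytest.fixture(scope="session")
def small_layout() -> MEALayout:
    """Twelve electrodes: 4x4 grid minus corners."""
    return standard_layout(4, 4)


@pytest.fixture
def worked_recording(quad_layout) -> Recording:
    """Hand-built 4-electrode, 60 s recording exercising every parameter.

    Electrode 11: three tight triplets (3 bursts/min, qualifies everywhere).
    Electrode 21: one triplet (1 burst/min: counts for network_size only).
    Electrode 12: sparse tonic spikes, no bursts.
    Electrode 22: silent.
    """
    T = 60.0
    trains = {
        "11": SpikeTrain("11", np.array([1.0, 1.05, 1.1,
                                         21.0, 21.05, 21.1,
                                         41.0, 41.05, 41.1]), T),
        "21": SpikeTrain("21", np.array([5.0, 5.08, 5.16]), T),
        "12": SpikeTrain("12", np.array([2.0, 12.0, 22.0, 32.0]), T),
        "22": SpikeTrain("22", np.empty(0), T),
    }
    return Recording(quad_layout, trains, T, div=9, condition="control",
                     culture_id="fix-01")
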