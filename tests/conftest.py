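import numpy as np
import pytest

from adcr import (DetectorArray, HomeRangeParams, Landscape, PatchSpec,
                  generate_patch_landscape, grid_detectors)


@pytest.fixture(scope="session")
def flat3() -> Landscape:
    """3x3 homogeneous landscape."""
    return Landscape(3, 3)


@pytest.fixture(scope="session")
def patchy15() -> Landscape:
    """15x15 binary patch landscape used across estimation tests."""
    return generate_patch_landscape(15, 15, PatchSpec(2, (20, 40), seed=5))


@pytest.fixture(scope="session")
def dets15(patchy15) -> DetectorArray:
    """5x5 detector grid inside the 15x15 landscape, 5 occasions."""
    return grid_detectors(patchy15, 3, 11, 2, K=5)


@pytest.fixture(scope="session")
def two_cell_world():
    """A 2-cell landscape with one detector: small enough for exhaustive oracles."""
    land = Landscape(2, 1)
    dets = DetectorArray(np.array([[0.5, 0.5]]), K=1)
    return land, dets


def random_homerange_params(rng: np.random.Generator) -> HomeRangeParams:
    return HomeRangeParams(rng.uniform(-1.0, 2.0), [rng.uniform(-2.0, 2.0)])
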