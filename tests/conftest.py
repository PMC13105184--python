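import numpy as np
import pytest

from stomanet.patterns import ObservationWindow, PointPattern

UNIT = ObservationWindow(0.0, 0.0, 1.0, 1.0)


@pytest.fixture
def unit_window() -> ObservationWindow:
    return UNIT


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def square_corners(unit_window) -> PointPattern:
    return PointPattern(
        np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]), unit_window
    )


def uniform_pattern(n: int, rng: np.random.Generator) -> PointPattern:
    return PointPattern(rng.random((n, 2)), UNIT, allow_duplicates=True)
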