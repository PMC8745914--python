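"""Shared fixtures: generated phantoms reused across test modules."""

import numpy as np
import pytest

from woundipi.phantom import PhantomSpec, generate


@pytest.fixture(scope="session")
def benign_phantom():
    """Default benign scene: every IPI sub-score should be zero."""
    return generate(PhantomSpec.from_features())


@pytest.fixture(scope="session")
def worst_phantom():
    """Scene triggering the maximal case of all four parameters."""
    return generate(
        PhantomSpec.from_features(
            n_cold_spots=5,
            delta_t=3.0,
            inhomogeneous=True,
            concentrated=True,
            margin_gap=True,
        )
    )


@pytest.fixture(scope="session")
def small_benign_phantom():
    """Quarter-area benign scene for fast CLI/IO tests."""
    return generate(PhantomSpec.from_features(size=(260, 348)))


def iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    return float((a & b).sum() / (a | b).sum())


@pytest.fixture(scope="session")
def iou_fn():
    return iou
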