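import numpy as np
import pytest

from planche import (
    BodyType,
    SegmentTable,
    build_grid,
    default_config,
)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def default_grid():
    return build_grid()


@pytest.fixture
def reference_body():
    return BodyType(race="european", gender="male", mass_kg=63.0, height_m=1.66)


def random_segment_table(rng: np.random.Generator) -> SegmentTable:
    """A random valid eight-segment table (not feasibility-filtered)."""
    lengths = rng.uniform(0.08, 0.5, size=8)
    return SegmentTable(
        masses_kg=rng.uniform(0.5, 12.0, size=8),
        lengths_m=lengths,
        cogs_m=lengths * rng.uniform(0.1, 0.9, size=8),
        hand_length_m=float(rng.uniform(0.05, 0.2)),
    )
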