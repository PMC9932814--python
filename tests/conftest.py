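import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from riqtl import core_io

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def toy_genotypes() -> core_io.GenotypeMatrix:
    """Six strains, four markers on two chromosomes, complete calls."""
    markers = [
        core_io.MarkerInfo("m1", "1", 0.0, 10.0),
        core_io.MarkerInfo("m2", "1", 20.0, 40.0),
        core_io.MarkerInfo("m3", "2", 0.0, 5.0),
        core_io.MarkerInfo("m4", "2", 15.0, 25.0),
    ]
    calls = np.array(
        [
            ["A", "A", "A", "B"],
            ["A", "A", "B", "B"],
            ["A", "B", "A", "A"],
            ["B", "B", "B", "A"],
            ["B", "A", "A", "B"],
            ["B", "B", "B", "A"],
        ]
    )
    return core_io.GenotypeMatrix([f"s{i}" for i in range(6)], markers, calls)


@pytest.fixture
def single_marker_genotypes() -> core_io.GenotypeMatrix:
    return core_io.GenotypeMatrix(
        [f"s{i}" for i in range(6)],
        [core_io.MarkerInfo("m1", "1", 0.0, 10.0)],
        np.array([["A"], ["A"], ["A"], ["B"], ["B"], ["B"]]),
    )
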