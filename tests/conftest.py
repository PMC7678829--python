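import numpy as np
import pytest

from myowave.benchmark import run_segmentation_benchmark
from myowave.synthetic import BoundarySpec, generate_image_sequence


@pytest.fixture(scope="session")
def benchmark_result():
    """The standard 100-frame segmentation benchmark (seed 42), run once."""
    return run_segmentation_benchmark(seed=42)


@pytest.fixture(scope="session")
def small_oscillation_scene():
    """A short 8 Hz / 1 mm oscillation scene shared across segmentation tests."""
    superficial = BoundarySpec(c0=150.0, c1=0.02, components=[(8.0, 1.0, 0.3)])
    deep = BoundarySpec(c0=350.0, c1=0.01, components=[(8.0, 0.8, 1.1)])
    return generate_image_sequence(superficial, deep, n_frames=60, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
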