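import numpy as np
import pytest

from centerfind.arena import SHAPE_SPECS, build_arena


@pytest.fixture(scope="session")
def arenas():
    return {name: build_arena(spec) for name, spec in SHAPE_SPECS.items()}


@pytest.fixture(scope="session")
def circle_arena(arenas):
    return arenas["circle"]


@pytest.fixture(scope="session")
def square_arena(arenas):
    return arenas["square"]


@pytest.fixture(scope="session")
def small_session():
    """A small rendered session shared by pipeline-level tests."""
    from centerfind.simulate import SessionConfig, gen_session

    cfg = SessionConfig(shape="circle", n_animals=4, n_trials=6, seed=42)
    return gen_session(cfg)


@pytest.fixture(scope="session")
def benchmark_features(circle_arena):
    """High-separation archetype benchmark, featurized, with its DTW matrix."""
    from centerfind.approach import minmax_scale
    from centerfind.arena import distance_to_perimeter
    from centerfind.dtw import dtw_matrix
    from centerfind.simulate import gen_cluster_benchmark

    paths, labels = gen_cluster_benchmark(20, circle_arena, "high", seed=1)
    series = [
        minmax_scale(distance_to_perimeter(circle_arena, p.positions())) for p in paths
    ]
    return series, labels, dtw_matrix(series)


def rng(seed=0):
    return np.random.default_rng(seed)
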