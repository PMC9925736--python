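import numpy as np
import pytest

from porcimetry.synthetic import (
    SceneSpec,
    compose_scene,
    cylinder_pig,
    generate_pig_cloud,
    standard_pig,
)


@pytest.fixture(scope="session")
def standard_pig_params():
    return standard_pig()


@pytest.fixture(scope="session")
def dense_pig(standard_pig_params):
    """Zero-noise 1e5-point standard pig with its ground truth."""
    return generate_pig_cloud(standard_pig_params, 100_000, 0.0, seed=1)


@pytest.fixture(scope="session")
def dense_cylinder_pig():
    """Zero-noise cylinder pig (radius 0.3 m): the geometry oracle shape."""
    return generate_pig_cloud(cylinder_pig(radius=0.3), 100_000, 0.0, seed=2)


@pytest.fixture(scope="session")
def labeled_scene(standard_pig_params):
    """A full labeled pen scene at the default study conditions."""
    cloud, truth = generate_pig_cloud(standard_pig_params, 20_000, 0.002, seed=0)
    spec = SceneSpec(seed=0)
    points, labels = compose_scene(cloud, spec)
    return points, labels, truth


def rel_err(a: float, b: float) -> float:
    return abs(a - b) / abs(b)
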