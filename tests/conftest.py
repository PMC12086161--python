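import numpy as np
import pytest

from greenprompt import (
    ProposalConfig,
    SceneConfig,
    generate_proposals,
    generate_scene,
)


@pytest.fixture(scope="session")
def small_scene():
    """A 5-plant scene reused by read-only tests."""
    return generate_scene(SceneConfig(n_plants=5, seed=42))


@pytest.fixture(scope="session")
def small_scene_proposals(small_scene):
    return generate_proposals(small_scene, ProposalConfig(seed=42))


def make_battery(seed: int, n_scenes: int, plant_range=(5, 13)):
    """Seeded scenes with plant counts drawn uniformly from the range."""
    rng = np.random.default_rng(seed)
    scenes = []
    for k in range(n_scenes):
        n = int(rng.integers(*plant_range))
        scenes.append(generate_scene(SceneConfig(n_plants=n, seed=1000 + seed + k)))
    return scenes


@pytest.fixture(scope="session")
def battery10():
    return make_battery(seed=7, n_scenes=10)
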