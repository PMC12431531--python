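import numpy as np
import pytest

from pigstressnet.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 160px scene with a few pigs."""
    return generate_scene(SceneSpec(image_size=160, n_pigs=3, seed=11))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Eight small scenes for smoke training."""
    items = []
    for s in range(8):
        items.append(generate_scene(SceneSpec(image_size=160, n_pigs=2, seed=100 + s)))
    return items


def random_boxes(rng, n, lo=0.0, hi=100.0, min_side=1.0):
    """n valid xyxy boxes."""
    x1 = rng.uniform(lo, hi - min_side, n)
    y1 = rng.uniform(lo, hi - min_side, n)
    w = rng.uniform(min_side, hi / 3, n)
    h = rng.uniform(min_side, hi / 3, n)
    return np.stack([x1, y1, np.minimum(x1 + w, hi + 40), np.minimum(y1 + h, hi + 40)], axis=1)
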