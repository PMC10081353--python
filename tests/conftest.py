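import numpy as np
import pytest

from jetmap.swc_io import arc_length_parameterize
from jetmap.synthetic import GaussianBumpTransform, random_bump_transform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def y_tree_swc(tmp_path):
    """Y-shaped tree: root->a is 10, a->b is 10 (total 20), a->c is 5 (total 15)."""
    text = "\n".join([
        "# y tree",
        "1 1 0 0 0 1 -1",
        "2 3 10 0 0 1 1",
        "3 3 20 0 0 1 2",
        "4 3 13 4 0 1 2",
    ])
    path = tmp_path / "y.swc"
    path.write_text(text + "\n")
    return path


def bumps_along(points: np.ndarray, seed: int, n: int = 3,
                amplitude: float = 20.0, sigma: float = 80.0) -> GaussianBumpTransform:
    """Random smooth diffeomorphism whose bumps overlap the given points."""
    rng = np.random.default_rng(seed)
    return random_bump_transform(rng, n_bumps=n, amplitude=amplitude,
                                 sigma=sigma, near=points)


def random_polyline(rng: np.random.Generator, n_knots: int = 12,
                    step: float = 20.0):
    """Random regular polyline with roughly `step`-micron segments."""
    steps = rng.normal(size=(n_knots - 1, 3))
    steps = steps / np.linalg.norm(steps, axis=1, keepdims=True) * \
        rng.uniform(0.5 * step, 1.5 * step, (n_knots - 1, 1))
    knots = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return arc_length_parameterize(knots)
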