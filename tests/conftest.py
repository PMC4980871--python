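import numpy as np
import pytest

from idgraph import ShapeSpec, sample_hypersphere_surface


@pytest.fixture(scope="session")
def sphere_arcs():
    """Cached analytic-geodesic hypersphere samples keyed by (D, N, seed)."""
    cache = {}

    def factory(dim, n_points, seed=1):
        key = (dim, n_points, seed)
        if key not in cache:
            spec = ShapeSpec("hypersphere", dim=dim, n_points=n_points,
                             seed=seed)
            _, arcs = sample_hypersphere_surface(spec)
            cache[key] = arcs
        return cache[key]

    return factory


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
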