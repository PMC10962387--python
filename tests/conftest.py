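import numpy as np
import pytest

from tractokit import BundleSpec, PhantomSpec, make_phantom, phantom_atlas


def random_polyline(rng, npoints=None, scale=50.0):
    """Jagged random polyline: cumulative random steps (a random walk)."""
    n = npoints or int(rng.integers(5, 60))
    steps = rng.normal(scale=scale / n, size=(n, 3))
    return np.cumsum(steps, axis=0) + rng.uniform(-scale, scale, size=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240311)


@pytest.fixture(scope="session")
def three_bundle_spec():
    """Three well-separated bundles, jitter 0.5 mm, variable point counts."""
    return PhantomSpec(bundles=[
        BundleSpec(kind="line", params={"start": (0, 0, 0)}, n_fibers=60,
                   jitter_sd=0.5, npoints_range=(10, 40)),
        BundleSpec(kind="arc", params={"center": (0, 70, 0)}, n_fibers=60,
                   jitter_sd=0.5, npoints_range=(10, 40)),
        BundleSpec(kind="u_shape", params={"center": (90, 0, 0)}, n_fibers=60,
                   jitter_sd=0.5, npoints_range=(10, 40)),
    ], seed=42)


@pytest.fixture(scope="session")
def three_bundle_phantom(three_bundle_spec):
    return make_phantom(three_bundle_spec)


@pytest.fixture(scope="session")
def three_bundle_atlas(three_bundle_spec):
    return phantom_atlas(three_bundle_spec)  # threshold = 3 * jitter_sd
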