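import numpy as np
import pytest

from lamseg.phantom import LayerSpec, PhantomSpec, generate_phantom


def make_tiny_spec(n_slices: int = 6, seed: int = 0,
                   size: int = 160) -> PhantomSpec:
    """Three well-separated layers on a small grid — fast unit-test phantom."""
    layers = (
        LayerSpec(1, (0.9,) * n_slices, dot_density=20.0, dot_radius_px=1.5),
        LayerSpec(2, (0.6,) * n_slices, dot_density=300.0, dot_radius_px=2.0),
        LayerSpec(3, (0.3,) * n_slices, dot_density=2500.0, dot_radius_px=1.5),
    )
    return PhantomSpec(size, size, n_slices, layers, seed=seed)


@pytest.fixture(scope="session")
def tiny_spec():
    return make_tiny_spec()


@pytest.fixture(scope="session")
def tiny_phantom(tiny_spec):
    return generate_phantom(tiny_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
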