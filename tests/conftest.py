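import numpy as np
import pytest

from ctcomp import (
    AdiposeDepot,
    BoneElement,
    MouseSpec,
    PhantomSpec,
    TailSpec,
    VoxelGrid,
    simulate_mouse,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_grid(rng):
    """A small random HU grid spanning all tissue windows."""
    data = rng.uniform(-1024, 4000, size=(8, 8, 8)).astype(np.float32)
    return VoxelGrid(data, 250.0)


@pytest.fixture(scope="session")
def tiny_mouse():
    """A small noise-free digital mouse, shared across tests (cheap)."""
    spec = MouseSpec(
        body_semiaxes_mm=(10.0, 4.0, 4.0),
        depots=[
            AdiposeDepot((0.0, 0.0, 0.0), (9.4, 3.4, 3.4), "subcutaneous", 1.0,
                         z_range_mm=(-7.5, 8.0)),
            AdiposeDepot((3.0, 0.0, 0.0), (2.0, 1.4, 1.4)),
        ],
        bones=[BoneElement((0.0, 0.0, 0.0), 0.8, 16.0)],
        tail=TailSpec(radius_mm=0.8, length_mm=8.0),
        noise_sd_hu=0.0,
        seed=7,
    )
    grid, truth = simulate_mouse(spec, edge_um=250.0, supersample=2)
    return grid, truth


@pytest.fixture
def noise_free_phantom_spec():
    return PhantomSpec(oil_mass_g=9.0, noise_sd_hu=0.0, seed=1)
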