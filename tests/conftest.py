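import numpy as np
import pytest

from bryoclim.geo import ClimateStack, GridTransform, RegionMask
from bryoclim.synth import LandscapeSpec, VariableDef, generate_landscape


def make_stack(
    variables: dict, elevation=None, west=-20.0, north=35.0, cell=0.01, valid=None
) -> ClimateStack:
    """Build a stack directly from arrays (no landscape generation)."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in variables.items()}
    shape = next(iter(arrays.values())).shape
    if elevation is None:
        elevation = np.zeros(shape)
    if valid is None:
        valid = np.ones(shape, dtype=bool)
    return ClimateStack(
        variables=arrays,
        elevation=np.asarray(elevation, dtype=float),
        transform=GridTransform(west, north, cell),
        valid_mask=valid,
    )


def single_region_mask(shape, archipelagos: int = 1) -> RegionMask:
    """Everything is one island (or several horizontal island bands)."""
    island = np.zeros(shape, dtype=int)
    arch = np.zeros(shape, dtype=int)
    n_rows = shape[0]
    bands = max(archipelagos, 1)
    for b in range(bands):
        rows = slice(b * n_rows // bands, (b + 1) * n_rows // bands)
        island[rows, :] = b + 1
        arch[rows, :] = b + 1
    return RegionMask(
        island_id=island, archipelago_id=arch, continent=np.zeros(shape, dtype=bool)
    )


@pytest.fixture(scope="session")
def small_landscape():
    """A 60x60 3-island landscape shared by read-only tests."""
    spec = LandscapeSpec(seed=11, n_rows=60, n_cols=60, n_islands=3, n_archipelagos=2)
    return generate_landscape(spec)


@pytest.fixture(scope="session")
def noise_free_landscape():
    """Deterministic lapse-rate-only landscape (no noise), one island."""
    vdefs = (
        VariableDef("BIO5", 26.5, -0.0065, 0.0, 1.0),
        VariableDef("BIO13", 60.0, 0.05, 0.0, 1.0),
    )
    spec = LandscapeSpec(
        seed=4, n_rows=80, n_cols=80, n_islands=1, n_archipelagos=1, variable_defs=vdefs
    )
    return generate_landscape(spec)
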