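import numpy as np
import pytest

from hypersample.covariates import CovariateLayer, CovariateStack
from hypersample.raster import GridTransform
from hypersample.synthetic import LandscapeSpec, make_landscape

CRS = "EPSG:28355"


def stack_from_arrays(arrays, kinds=None, names=None, cell=1.0, origin=(0.0, None)):
    """Build a stack directly from 2-D arrays (test helper)."""
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    kinds = kinds or ["continuous"] * len(arrays)
    names = names or [f"v{i}" for i in range(len(arrays))]
    ny = arrays[0].shape[0]
    y0 = origin[1] if origin[1] is not None else ny * cell
    transform = GridTransform(origin[0], y0, cell, cell)
    layers = [CovariateLayer(n, k, a) for n, k, a in zip(names, kinds, arrays)]
    return CovariateStack(layers, transform, crs=CRS)


def tiny_stack(r, seed, ncov=2):
    """1 x r stack of correlated continuous covariates for brute-force work."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(1, r))
    arrays = [base]
    for _ in range(ncov - 1):
        arrays.append(0.5 * base + rng.normal(size=(1, r)))
    return stack_from_arrays(arrays)


@pytest.fixture(scope="session")
def small_landscape():
    """40x40, 3 continuous + 1 categorical, 2% nodata."""
    spec = LandscapeSpec(shape=(40, 40), n_continuous=3, n_categorical=1,
                         ranges=4.0, nodata_fraction=0.02, seed=11)
    return make_landscape(spec)


@pytest.fixture(scope="session")
def plain_landscape():
    """60x60, 4 continuous covariates, full mask."""
    spec = LandscapeSpec(shape=(60, 60), n_continuous=4, ranges=5.0, seed=7)
    return make_landscape(spec)
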