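"""Seeded synthetic landscapes and legacy designs for testing and demos.

Continuous covariates are smoothed Gaussian random fields: white-noise
fields are first mixed by the Cholesky factor of a target correlation
matrix, then smoothed with a Gaussian kernel whose width sets the spatial
autocorrelation range.  Smoothing attenuates the imposed correlation only
mildly, so the realized Pearson correlation approximates the target.
Categorical layers come from quantile-thresholding an auxiliary smoothed
field, which yields spatially coherent classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

from .covariates import CATEGORICAL, CONTINUOUS, CovariateLayer, CovariateStack, SampleDesign
from .raster import GridTransform


@dataclass
class LandscapeSpec:
    shape: tuple[int, int] = (100, 100)
    n_continuous: int = 5
    correlation: np.ndarray | None = None   # target, unit diagonal, PSD
    ranges: tuple | float = 5.0             # smoothing kernel sigma (cells), scalar or per layer
    n_categorical: int = 0
    class_counts: tuple = ()
    nodata_fraction: float = 0.0
    cell_size: float = 10.0                 # meters
    origin: tuple[float, float] = (500000.0, 6000000.0)
    seed: int | tuple = 0

    def validate(self) -> None:
        if self.shape[0] < 2 or self.shape[1] < 2:
            raise ValueError("shape must be at least 2x2")
        if self.n_continuous < 1:
            raise ValueError("need at least one continuous covariate")
        if not 0 <= self.nodata_fraction < 1:
            raise ValueError("nodata_fraction must lie in [0, 1)")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            if corr.shape != (self.n_continuous, self.n_continuous):
                raise ValueError("correlation matrix shape mismatch")
            if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
                raise ValueError("correlation must be symmetric with unit diagonal")
            eig = np.linalg.eigvalsh(corr)
            if eig.min() < -1e-10:
                raise ValueError("correlation matrix is not positive semi-definite")


def _smooth_field(noise: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return noise
    out = scipy.ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    return (out - out.mean()) / out.std()


def make_landscape(spec: LandscapeSpec) -> CovariateStack:
    """Generate a covariate stack per the spec; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape
    kc = spec.n_continuous
    noise = rng.standard_normal((kc, ny, nx))
    if spec.correlation is not None:
        corr = np.asarray(spec.correlation, dtype=float)
        # small PSD jitter tolerated; mix BEFORE smoothing
        L = np.linalg.cholesky(corr + 1e-10 * np.eye(kc))
        noise = np.einsum("ij,jyx->iyx", L, noise)
    ranges = spec.ranges if np.ndim(spec.ranges) else [spec.ranges] * kc
    layers = []
    for i in range(kc):
        vals = _smooth_field(noise[i], float(ranges[i]))
        layers.append(CovariateLayer(name=f"cov{i + 1}", kind=CONTINUOUS, values=vals))

    counts = spec.class_counts or (3,) * spec.n_categorical
    for j in range(spec.n_categorical):
        aux = _smooth_field(rng.standard_normal((ny, nx)), float(np.atleast_1d(ranges)[0]))
        ncls = int(counts[j])
        edges = np.quantile(aux, np.linspace(0, 1, ncls + 1)[1:-1])
        codes = np.searchsorted(edges, aux).astype(float)
        layers.append(CovariateLayer(name=f"cat{j + 1}", kind=CATEGORICAL, values=codes))

    if spec.nodata_fraction > 0:
        n_bad = int(round(spec.nodata_fraction * ny * nx))
        flat = rng.choice(ny * nx, size=n_bad, replace=False)
        mask_rows, mask_cols = np.unravel_index(flat, (ny, nx))
        for layer in layers:
            layer.values[mask_rows, mask_cols] = np.nan

    transform = GridTransform(spec.origin[0], spec.origin[1], spec.cell_size, spec.cell_size)
    return CovariateStack(layers=layers, transform=transform, crs="EPSG:28355")


def make_legacy(stack: CovariateStack, n: int, bias: str = "none",
                seed: int | tuple = 0) -> SampleDesign:
    """Legacy designs with controlled sampling bias.

    bias='none': uniform over valid cells.  bias='spatial_corner': confined
    to the top-left map quadrant.  bias='covariate_low_tail': inclusion
    probability proportional to the rank-inverse of the first continuous
    covariate, concentrating sites in its low values.
    """
    rng = np.random.default_rng(seed)
    cells = stack.valid_cells()
    if bias == "none":
        eligible = np.arange(len(cells))
        probs = None
    elif bias == "spatial_corner":
        ny, nx = stack.shape
        in_corner = (cells[:, 0] < ny // 2) & (cells[:, 1] < nx // 2)
        eligible = np.nonzero(in_corner)[0]
        probs = None
    elif bias == "covariate_low_tail":
        first = stack.continuous_names[0]
        vals = stack[first].values[cells[:, 0], cells[:, 1]]
        ranks = np.argsort(np.argsort(vals)) + 1  # 1 = lowest value
        weights = 1.0 / ranks
        eligible = np.arange(len(cells))
        probs = weights / weights.sum()
    else:
        raise ValueError(f"unknown bias {bias!r}")
    if n > len(eligible):
        raise ValueError(f"n={n} exceeds the {len(eligible)} eligible cells")
    picks = rng.choice(eligible, size=n, replace=False, p=probs)
    return SampleDesign.from_cells(stack, cells[picks], provenance="grid")
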