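"""Count-of-observations (COOBS) coverage mapping.

For each pixel, the maximum Mahalanobis distance to every other valid pixel
(magpd) turns raw distances to the legacy points (dd) into standardized
scores sdd = 1 - dd/magpd in [0, 1]; the COOBS value is the number of legacy
observations whose sdd reaches a similarity threshold.  Low counts flag areas
of covariate space the legacy data does not cover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import CovariateStack, SampleDesign
from .distance import population_factor
from .errors import DegenerateStackError

DEFAULT_CLASSES = (0, 5, 10, 20, 40, np.inf)


@dataclass
class CoobsConfig:
    similarity_threshold: float = 0.975
    mode: str = "approximate"  # exact | approximate
    approx_sample: int = 2000
    seed: int | tuple = 0

    def validate(self) -> None:
        if not 0 < self.similarity_threshold < 1:
            raise ValueError("similarity_threshold must lie in (0, 1)")
        if self.mode not in ("exact", "approximate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "approximate" and self.approx_sample < 2:
            raise ValueError("approx_sample must be >= 2")


@dataclass
class CoverageMap:
    coobs: np.ndarray   # int raster, -1 off mask
    magpd: np.ndarray   # float raster, NaN off mask
    threshold: float


def _pairwise_max(whitened: np.ndarray, ref: np.ndarray, chunk: int = 512) -> np.ndarray:
    """max_j ||whitened_i - ref_j|| per row i, chunked to bound memory."""
    out = np.zeros(len(whitened))
    for start in range(0, len(whitened), chunk):
        block = whitened[start:start + chunk]
        d2 = (
            np.sum(block**2, axis=1)[:, None]
            + np.sum(ref**2, axis=1)[None, :]
            - 2.0 * block @ ref.T
        )
        out[start:start + chunk] = np.sqrt(np.maximum(d2.max(axis=1), 0.0))
    return out


def magpd_map(stack: CovariateStack, config: CoobsConfig) -> np.ndarray:
    """Per-pixel maximum Mahalanobis distance to all valid cells (exact), or
    to a seeded random subset (approximate; biased low by construction)."""
    config.validate()
    if stack.r < 2:
        raise DegenerateStackError("need at least 2 valid cells")
    factor = population_factor(stack)
    white = factor.whiten(stack.continuous_matrix())
    if config.mode == "approximate" and config.approx_sample < stack.r:
        rng = np.random.default_rng(config.seed)
        ref = white[rng.choice(stack.r, size=config.approx_sample, replace=False)]
    else:
        ref = white
    maxdist = _pairwise_max(white, ref)
    out = np.full(stack.shape, np.nan)
    cells = stack.valid_cells()
    out[cells[:, 0], cells[:, 1]] = maxdist
    return out


def coobs_map(stack: CovariateStack, legacy: SampleDesign, config: CoobsConfig,
              magpd: np.ndarray | None = None) -> CoverageMap:
    """COOBS count per pixel: legacy points with sdd = 1 - dd/magpd >= threshold.

    Pixels with magpd = 0 (identical to every other pixel) are flagged and
    counted by exact covariate match instead.
    """
    config.validate()
    if legacy.n == 0:
        raise ValueError("legacy design is empty")
    if magpd is None:
        magpd = magpd_map(stack, config)
    factor = population_factor(stack)
    cells = stack.valid_cells()
    white = factor.whiten(stack.continuous_matrix(cells))
    legacy_white = factor.whiten(legacy.table[stack.continuous_names].to_numpy(dtype=float))
    d2 = (
        np.sum(white**2, axis=1)[:, None]
        + np.sum(legacy_white**2, axis=1)[None, :]
        - 2.0 * white @ legacy_white.T
    )
    dd = np.sqrt(np.maximum(d2, 0.0))  # (r, o)
    mvals = magpd[cells[:, 0], cells[:, 1]]
    zero = mvals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} pixels have magpd = 0; using exact-match counts",
                      UserWarning)
    safe_m = np.where(zero, 1.0, mvals)
    sdd = 1.0 - dd / safe_m[:, None]
    counts = np.sum(sdd >= config.similarity_threshold, axis=1)
    counts = np.where(zero, np.sum(dd == 0, axis=1), counts)
    coobs = np.full(stack.shape, -1, dtype=int)
    coobs[cells[:, 0], cells[:, 1]] = counts
    return CoverageMap(coobs=coobs, magpd=magpd, threshold=config.similarity_threshold)


def coverage_crosstab(coverage: CoverageMap, sites: SampleDesign,
                      classes: tuple = DEFAULT_CLASSES) -> pd.Series:
    """Proportion of sites per coverage class (half-open [low, high), the top
    class closed above); proportions sum to 1."""
    vals = coverage.coobs[sites.cells[:, 0], sites.cells[:, 1]]
    if np.any(vals < 0):
        raise ValueError("some sites fall on masked pixels")
    edges = np.asarray(classes, dtype=float)
    idx = np.searchsorted(edges, vals, side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f">{lo:g}" if np.isinf(hi) else f"{lo:g}-{hi:g}")
    return pd.Series(counts / counts.sum(), index=labels, name="proportion")
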