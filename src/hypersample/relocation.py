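"""Alternative-site selection for inaccessible design points.

Given a site that cannot be visited, candidate replacement cells are taken
from a circular buffer around it, masked to cells whose categorical codes all
match the site's.  Mahalanobis distance in continuous-covariate space is
mapped to a similarity score by a negative sigmoid anchored at the median
buffer distance,

    S(d) = 1 - 1 / (1 + exp(-slope * (d - d_med))) ,

so S(d_med) = 0.5 and S is a strictly decreasing bijection onto (0, 1).  The
replacement is drawn from the cells whose similarity passes a threshold
(default 0.975).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import divergence
from .covariates import CovariateStack, SampleDesign
from .distance import MahalanobisFactor, population_factor
from .errors import EmptyZoneError, NoQualifierError, RelocationFailureWarning


@dataclass
class RelocationConfig:
    buffer_radius: float = 500.0
    similarity_threshold: float = 0.975
    strategy: str = "random"  # random | nearest | ranked
    slope: float = 1.0
    grow: bool = False
    grow_cap: float = 4.0
    seed: int | tuple = 0

    def validate(self) -> None:
        if self.buffer_radius <= 0:
            raise ValueError("buffer_radius must be > 0")
        if not 0 < self.similarity_threshold < 1:
            raise ValueError("similarity_threshold must lie in (0, 1)")
        if self.strategy not in ("random", "nearest", "ranked"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class SimilaritySurface:
    """Per-candidate distances and similarities within the masked buffer."""

    cells: np.ndarray            # (m, 2) candidate (row, col)
    distances: np.ndarray        # Mahalanobis dist_i
    similarities: np.ndarray
    dist_med: float
    radius_used: float


def similarity(dist, dist_med, slope: float = 1.0):
    """Negative-sigmoid similarity in (0, 1); equals 0.5 at the median."""
    d = np.asarray(dist, dtype=float)
    return 1.0 - 1.0 / (1.0 + np.exp(-slope * (d - dist_med)))


def qualifier_distance_cutoff(dist_med: float, threshold: float, slope: float = 1.0) -> float:
    """Closed-form inverse: similarity(d) >= t  <=>  d <= d_med + ln(1/t - 1)/slope."""
    return dist_med + np.log(1.0 / threshold - 1.0) / slope


def candidate_zone(stack: CovariateStack, site, config: RelocationConfig,
                   radius: float | None = None) -> np.ndarray:
    """Valid cells within the buffer radius of the site center, excluding the
    site itself and any cell whose categorical codes differ from the site's."""
    site = np.asarray(site, dtype=int)
    if not stack.mask[site[0], site[1]]:
        raise EmptyZoneError(f"site cell {tuple(site)} is not on the valid mask")
    radius = config.buffer_radius if radius is None else radius
    sx, sy = stack.transform.cell_center(site[0], site[1])
    # bounding window, then exact circle test on cell centers
    nrow, ncol = stack.shape
    rr = int(np.ceil(radius / stack.transform.dy)) + 1
    rc = int(np.ceil(radius / stack.transform.dx)) + 1
    r0, r1 = max(0, site[0] - rr), min(nrow, site[0] + rr + 1)
    c0, c1 = max(0, site[1] - rc), min(ncol, site[1] + rc + 1)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    rows, cols = rows.ravel(), cols.ravel()
    keep = stack.mask[rows, cols]
    rows, cols = rows[keep], cols[keep]
    x, y = stack.transform.cell_center(rows, cols)
    inside = (x - sx) ** 2 + (y - sy) ** 2 <= radius**2
    rows, cols = rows[inside], cols[inside]
    not_site = ~((rows == site[0]) & (cols == site[1]))
    rows, cols = rows[not_site], cols[not_site]
    for name in stack.categorical_names:
        vals = stack[name].values
        match = vals[rows, cols] == vals[site[0], site[1]]
        rows, cols = rows[match], cols[match]
    if len(rows) == 0:
        raise EmptyZoneError(
            f"no candidate cells within {radius} m of site {tuple(site)} after masking"
        )
    return np.column_stack([rows, cols])


def similarity_surface(stack: CovariateStack, site, config: RelocationConfig,
                       factor: MahalanobisFactor | None = None,
                       radius: float | None = None) -> SimilaritySurface:
    if factor is None:
        factor = population_factor(stack)
    radius = config.buffer_radius if radius is None else radius
    cells = candidate_zone(stack, site, config, radius=radius)
    site_vals = stack.continuous_matrix(np.asarray(site)[None, :])[0]
    dist = factor.distances(stack.continuous_matrix(cells), site_vals)
    dist_med = float(np.median(dist))
    sims = similarity(dist, dist_med, slope=config.slope)
    return SimilaritySurface(cells=cells, distances=dist, similarities=sims,
                             dist_med=dist_med, radius_used=radius)


def relocate(stack: CovariateStack, site, config: RelocationConfig,
             factor: MahalanobisFactor | None = None,
             rng: np.random.Generator | None = None):
    """Pick a replacement cell for one site.

    Returns ``(new_cell, surface)`` for strategies random/nearest, or
    ``(ranked_cells, surface)`` for strategy ranked (qualifiers ordered by
    increasing Mahalanobis distance).
    """
    config.validate()
    if factor is None:
        factor = population_factor(stack)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    site = np.asarray(site, dtype=int)

    radius = config.buffer_radius
    max_radius = config.buffer_radius * config.grow_cap
    while True:
        try:
            surf = similarity_surface(stack, site, config, factor=factor, radius=radius)
        except EmptyZoneError:
            if config.grow and radius * 2 <= max_radius:
                radius *= 2
                continue
            raise
        qual = surf.similarities >= config.similarity_threshold
        if qual.any():
            break
        if config.grow and radius * 2 <= max_radius:
            radius *= 2
            continue
        raise NoQualifierError(
            f"no candidate reaches similarity {config.similarity_threshold} "
            f"(max attained {surf.similarities.max():.6f})",
            max_similarity=float(surf.similarities.max()),
        )

    qcells = surf.cells[qual]
    if config.strategy == "ranked":
        order = np.argsort(surf.distances[qual], kind="stable")
        return qcells[order], surf
    if config.strategy == "nearest":
        qx, qy = stack.transform.cell_center(qcells[:, 0], qcells[:, 1])
        sx, sy = stack.transform.cell_center(site[0], site[1])
        geo = (qx - sx) ** 2 + (qy - sy) ** 2
        return qcells[int(np.argmin(geo))], surf
    return qcells[int(rng.integers(len(qcells)))], surf


def relocate_design(stack: CovariateStack, design: SampleDesign,
                    config: RelocationConfig, on_fail: str = "error") -> SampleDesign:
    """Relocate every site of a design (random or nearest strategy).

    ``on_fail='keep'`` retains the original cell with a warning when a site
    has no qualifying replacement; ``'error'`` propagates the failure.
    """
    config.validate()
    if config.strategy == "ranked":
        raise ValueError("relocate_design requires a single-site strategy (random/nearest)")
    factor = population_factor(stack)
    rng = np.random.default_rng(config.seed)
    new_cells = []
    provenance = []
    for i in range(design.n):
        try:
            cell, _ = relocate(stack, design.cells[i], config, factor=factor, rng=rng)
            new_cells.append(cell)
            provenance.append("relocated")
        except (NoQualifierError, EmptyZoneError) as exc:
            if on_fail != "keep":
                raise
            warnings.warn(f"site {i}: {exc}; keeping original location",
                          RelocationFailureWarning)
            new_cells.append(design.cells[i])
            provenance.append(design.provenance[i])
    return SampleDesign.from_cells(stack, np.array(new_cells), provenance=provenance,
                                   ids=design.ids)


def evaluate_relocation(stack: CovariateStack, original: SampleDesign,
                        relocated: SampleDesign,
                        nbins: int = divergence.DEFAULT_NBINS) -> pd.DataFrame:
    """Per-covariate KL of both designs against the population, with a delta
    column and a trailing mean row."""
    if original.n != relocated.n:
        raise ValueError("original and relocated designs differ in size")
    kl_orig, mean_orig = divergence.mean_divergence(stack, original, nbins=nbins, metric="kl")
    kl_relo, mean_relo = divergence.mean_divergence(stack, relocated, nbins=nbins, metric="kl")
    df = pd.DataFrame({"kl_original": kl_orig, "kl_relocated": kl_relo})
    df.loc["mean"] = [mean_orig, mean_relo]
    df["delta"] = df["kl_relocated"] - df["kl_original"]
    return df
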