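"""Adapted hypercube evaluation of a legacy sample (aHELS).

Marginal quantile strata are built per continuous covariate; the density of
grid pixels and of legacy observations is tallied per stratum; the ratio
(observation density / pixel density) ranks strata from most under-sampled
upward; new sites are then allocated walking that ranking, drawing each
batch at random from the unselected cells of the triggering stratum, until
the budget s is spent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clhs import _stratum_index
from .covariates import CovariateStack, SampleDesign
from .errors import DegenerateStrataWarning, OutOfBoundsError, PartialAllocationWarning


@dataclass
class QuantileMatrix:
    """(s+1) x k matrix of per-covariate quantile boundaries; row 0 and row s
    are the covariate minima and maxima."""

    edges: np.ndarray
    names: list[str]

    @property
    def s(self) -> int:
        return self.edges.shape[0] - 1

    @property
    def k(self) -> int:
        return self.edges.shape[1]


@dataclass
class DensityTables:
    grid_density: np.ndarray  # (s, k): pixel tally / r
    data_density: np.ndarray  # (s, k): legacy tally / o
    ratio: np.ndarray         # data / grid, 0/0 -> 0
    o: int
    r: int


def quantile_matrix(stack: CovariateStack, s: int) -> QuantileMatrix:
    """Empirical quantiles (linear interpolation) at probabilities 0, 1/s,
    ..., 1 for each continuous covariate."""
    if s < 1:
        raise ValueError("s must be >= 1")
    names = stack.continuous_names
    if not names:
        raise ValueError("aHELS requires at least one continuous covariate")
    probs = np.linspace(0.0, 1.0, s + 1)
    cols = []
    for name in names:
        e = np.quantile(stack[name].values[stack.mask], probs)
        if len(np.unique(e)) < len(e):
            warnings.warn(f"covariate {name!r}: zero-width strata for s={s}",
                          DegenerateStrataWarning)
        cols.append(e)
    return QuantileMatrix(edges=np.column_stack(cols), names=list(names))


def _tally(values_by_col: np.ndarray, qm: QuantileMatrix) -> np.ndarray:
    """(s, k) stratum tallies for a (m, k) value matrix (half-open strata,
    last closed)."""
    s = qm.s
    out = np.zeros((s, qm.k))
    for j in range(qm.k):
        idx = _stratum_index(values_by_col[:, j], qm.edges[:, j])
        out[:, j] = np.bincount(idx, minlength=s)
    return out


def densities(stack: CovariateStack, legacy: SampleDesign, qm: QuantileMatrix) -> DensityTables:
    """Grid vs legacy data density per stratum, and their ratio."""
    if legacy.n == 0:
        raise ValueError("legacy design is empty")
    on_mask = stack.mask[legacy.cells[:, 0], legacy.cells[:, 1]]
    if not np.all(on_mask):
        bad = np.nonzero(~on_mask)[0]
        raise OutOfBoundsError(f"legacy points off the valid mask: ids {bad.tolist()}")
    grid_vals = np.column_stack([stack[n].values[stack.mask] for n in qm.names])
    data_vals = legacy.table[qm.names].to_numpy(dtype=float)
    grid_tally = _tally(grid_vals, qm)
    data_tally = _tally(data_vals, qm)
    grid_density = grid_tally / stack.r
    data_density = data_tally / legacy.n
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(grid_density > 0, data_density / np.where(grid_density > 0, grid_density, 1.0), 0.0)
        ratio = np.where((grid_density == 0) & (data_density > 0), np.inf, ratio)
    return DensityTables(grid_density=grid_density, data_density=data_density,
                         ratio=ratio, o=legacy.n, r=stack.r)


def rank_strata(tables: DensityTables) -> np.ndarray:
    """All (row, col) stratum indices ordered by increasing density ratio;
    ties broken by (column index, row index)."""
    s, k = tables.ratio.shape
    rows, cols = np.mgrid[0:s, 0:k]
    rows, cols = rows.ravel(), cols.ravel()
    order = np.lexsort((rows, cols, tables.ratio.ravel()))
    return np.column_stack([rows[order], cols[order]])


@dataclass
class AllocationResult:
    design: SampleDesign
    assignments: pd.DataFrame  # one row per site: stratum covariate/row, legacy ratio
    tables: DensityTables
    qm: QuantileMatrix


def allocate(stack: CovariateStack, legacy: SampleDesign, s: int,
             seed: int | tuple = 0, subtract_existing: bool = True) -> AllocationResult:
    """Allocate s new sites to the most under-sampled marginal strata.

    Walking the ranked ratios smallest-first, each stratum receives
    m = max(1, ceil(o*grid_density - combined data tally)) sites (capped at
    the remaining budget and at the stratum's unselected cells), drawn
    uniformly at random.  With ``subtract_existing=False`` the batch size is
    the literal m = max(1, ceil(o*grid_density)) regardless of how many
    observations the stratum already holds.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    rng = np.random.default_rng(seed)
    qm = quantile_matrix(stack, s)
    tables = densities(stack, legacy, qm)
    ranking = rank_strata(tables)

    cells = stack.valid_cells()
    grid_vals = np.column_stack([stack[n].values[cells[:, 0], cells[:, 1]] for n in qm.names])
    strata_of_cell = np.column_stack([
        _stratum_index(grid_vals[:, j], qm.edges[:, j]) for j in range(qm.k)
    ])
    legacy_flat = set(map(tuple, legacy.cells.tolist()))
    selected = np.zeros(len(cells), dtype=bool)
    # legacy cells are not eligible for reselection
    for i, cell in enumerate(cells):
        if (int(cell[0]), int(cell[1])) in legacy_flat:
            selected[i] = True

    o = tables.o
    combined_tally = tables.data_density * o  # legacy tallies; updated as sites land
    remaining = s
    chosen = []
    records = []

    while remaining > 0:
        progressed = False
        for row, col in ranking:
            if remaining <= 0:
                break
            target = o * tables.grid_density[row, col]
            have = combined_tally[row, col] if subtract_existing else 0.0
            m = max(1, int(np.ceil(target - have)))
            pool = np.nonzero((strata_of_cell[:, col] == row) & ~selected)[0]
            if len(pool) == 0:
                continue
            m = min(m, remaining, len(pool))
            picks = rng.choice(pool, size=m, replace=False)
            selected[picks] = True
            chosen.extend(picks.tolist())
            combined_tally += _tally(grid_vals[picks], qm)
            for p in picks:
                records.append({
                    "covariate": qm.names[col],
                    "stratum_row": int(row),
                    "stratum": f"{qm.names[col]}[q{int(row)}]",
                    "legacy_ratio": float(tables.ratio[row, col]),
                })
            remaining -= m
            progressed = True
        if not progressed:
            warnings.warn(
                f"allocation budget unfillable: {remaining} of {s} sites not placed",
                PartialAllocationWarning,
            )
            break

    design = SampleDesign.from_cells(stack, cells[np.array(chosen, dtype=int)],
                                     provenance="ahels")
    return AllocationResult(design=design, assignments=pd.DataFrame(records),
                            tables=tables, qm=qm)
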