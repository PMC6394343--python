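"""Conditioned Latin hypercube sampling by simulated annealing.

Sites are drawn from the valid cells of a covariate stack so that the design
simultaneously (1) places one point in each of n equal-probability marginal
strata of every continuous covariate, (2) matches the class proportions of
every categorical covariate, and (3) matches the Pearson correlation matrix
of the continuous covariates.  The weighted sum of the three mismatch terms
is minimized by Metropolis annealing starting from a random feasible sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import CovariateStack, SampleDesign
from .errors import ConstantCovariateWarning, DegenerateStrataWarning, InfeasibleError


@dataclass
class CLHSConfig:
    n: int
    iterations: int = 10000
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    temperature_start: float = 1.0
    cooling_rate: float = 0.95
    chain_length: int = 10
    swap_probability: float = 0.5
    seed: int | tuple = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if any(w < 0 for w in self.weights) or not any(self.weights):
            raise ValueError("weights must be nonnegative and not all zero")
        if not 0 < self.swap_probability < 1:
            raise ValueError("swap_probability must lie in (0, 1)")
        if not 0 < self.cooling_rate <= 1:
            raise ValueError("cooling_rate must lie in (0, 1]")


@dataclass
class StratumEdges:
    """Quantile stratum boundaries per continuous covariate and population
    class proportions per categorical covariate, for a given sample size n."""

    n: int
    edges: dict[str, np.ndarray]
    class_proportions: dict[str, np.ndarray]
    categories: dict[str, tuple]


@dataclass
class CLHSResult:
    design: SampleDesign
    objective: float
    components: tuple[float, float, float]  # (O1 continuous, O2 categorical, O3 correlation)
    objective_trace: np.ndarray
    config: CLHSConfig = field(repr=False, default=None)


def build_strata(stack: CovariateStack, n: int) -> StratumEdges:
    """n equal-probability strata per continuous covariate (empirical
    quantiles, linear interpolation) and population class proportions per
    categorical covariate."""
    if n < 1:
        raise ValueError("n must be >= 1")
    probs = np.linspace(0.0, 1.0, n + 1)
    edges = {}
    for name in stack.continuous_names:
        vals = stack[name].values[stack.mask]
        e = np.quantile(vals, probs)
        if len(np.unique(e)) < len(e):
            warnings.warn(
                f"covariate {name!r}: duplicate stratum edges for n={n}",
                DegenerateStrataWarning,
            )
        edges[name] = e
    props, cats = {}, {}
    for name in stack.categorical_names:
        layer = stack[name]
        vals = layer.values[stack.mask].astype(int)
        counts = np.array([(vals == c).sum() for c in layer.categories], dtype=float)
        props[name] = counts / counts.sum()
        cats[name] = layer.categories
    return StratumEdges(n=n, edges=edges, class_proportions=props, categories=cats)


def _stratum_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open strata [low, high), last stratum closed above."""
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def _o1(strata_idx: np.ndarray, n: int) -> float:
    # strata_idx: (n_sample, k_cont) stratum membership
    total = 0.0
    for j in range(strata_idx.shape[1]):
        counts = np.bincount(strata_idx[:, j], minlength=n)
        total += np.abs(counts - 1).sum()
    return float(total)


def _o2(code_idx: np.ndarray, pop_props: list[np.ndarray]) -> float:
    m = code_idx.shape[0]
    total = 0.0
    for j, props in enumerate(pop_props):
        counts = np.bincount(code_idx[:, j], minlength=len(props))
        total += np.abs(counts / m - props).sum()
    return float(total)


def _o3(cont_vals: np.ndarray, pop_corr: np.ndarray, flag: bool = False) -> float:
    k = cont_vals.shape[1]
    if k < 2 or cont_vals.shape[0] < 2:
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        samp = np.corrcoef(cont_vals, rowvar=False)
    diff = np.abs(pop_corr - samp)
    bad = ~np.isfinite(diff)
    if bad.any():
        if flag:
            warnings.warn(
                "constant covariate in sample: correlation terms treated as zero deviation",
                ConstantCovariateWarning,
            )
        diff = np.where(bad, 0.0, diff)
    iu = np.triu_indices(k, k=1)
    return float(diff[iu].sum())


def objective(sample_table: pd.DataFrame, edges: StratumEdges,
              population_correlation: np.ndarray,
              weights: tuple[float, float, float] = (1.0, 1.0, 1.0)):
    """Evaluate the three-component cLHS objective for a sample table.

    Returns ``(O1, O2, O3, total)`` with ``total = w1*O1 + w2*O2 + w3*O3``.
    The sample size must equal the n used to build the strata.
    """
    cont_names = list(edges.edges)
    cat_names = list(edges.class_proportions)
    m = len(sample_table)
    if m != edges.n:
        raise ValueError(f"sample size {m} != stratum count n={edges.n}")
    if cont_names:
        strata_idx = np.column_stack([
            _stratum_index(sample_table[nm].to_numpy(dtype=float), edges.edges[nm])
            for nm in cont_names
        ])
        o1 = _o1(strata_idx, edges.n)
        cont_vals = sample_table[cont_names].to_numpy(dtype=float)
        o3 = _o3(cont_vals, population_correlation, flag=True)
    else:
        o1, o3 = 0.0, 0.0
    if cat_names:
        code_idx = np.column_stack([
            np.searchsorted(np.asarray(edges.categories[nm]),
                            sample_table[nm].to_numpy(dtype=int))
            for nm in cat_names
        ])
        o2 = _o2(code_idx, [edges.class_proportions[nm] for nm in cat_names])
    else:
        o2 = 0.0
    w1, w2, w3 = weights
    return o1, o2, o3, w1 * o1 + w2 * o2 + w3 * o3


class _Annealer:
    """Internal state for the Metropolis search over cell indices."""

    def __init__(self, stack: CovariateStack, edges: StratumEdges, weights):
        cells = stack.valid_cells()
        self.cells = cells
        self.n = edges.n
        self.weights = weights
        cont_names = list(edges.edges)
        cat_names = list(edges.class_proportions)
        self.cont_vals = stack.continuous_matrix(cells)
        # precompute per-cell stratum / class membership for the whole grid
        if cont_names:
            self.strata = np.column_stack([
                _stratum_index(stack[nm].values[cells[:, 0], cells[:, 1]], edges.edges[nm])
                for nm in cont_names
            ])
        else:
            self.strata = np.empty((len(cells), 0), dtype=int)
        if cat_names:
            self.codes = np.column_stack([
                np.searchsorted(np.asarray(edges.categories[nm]),
                                stack[nm].values[cells[:, 0], cells[:, 1]].astype(int))
                for nm in cat_names
            ])
        else:
            self.codes = np.empty((len(cells), 0), dtype=int)
        self.pop_props = [edges.class_proportions[nm] for nm in cat_names]
        self.pop_corr = stack.population_correlation()

    def evaluate(self, idx: np.ndarray):
        o1 = _o1(self.strata[idx], self.n) if self.strata.shape[1] else 0.0
        o2 = _o2(self.codes[idx], self.pop_props) if self.codes.shape[1] else 0.0
        o3 = _o3(self.cont_vals[idx], self.pop_corr) if self.cont_vals.shape[1] else 0.0
        w1, w2, w3 = self.weights
        return o1, o2, o3, w1 * o1 + w2 * o2 + w3 * o3

    def worst_point(self, idx: np.ndarray) -> int:
        """Position (in idx) of the sample point contributing most to O1
        through over-filled strata."""
        if not self.strata.shape[1]:
            return 0
        overfill = np.zeros(len(idx))
        for j in range(self.strata.shape[1]):
            counts = np.bincount(self.strata[idx, j], minlength=self.n)
            overfill += np.maximum(counts[self.strata[idx, j]] - 1, 0)
        return int(np.argmax(overfill))


def clhs(stack: CovariateStack, config: CLHSConfig) -> CLHSResult:
    """Run conditioned Latin hypercube sampling and return the best-so-far
    design.  Fully deterministic for a fixed ``config.seed``."""
    config.validate()
    if config.n > stack.r:
        raise InfeasibleError(f"n={config.n} exceeds the {stack.r} valid cells")
    edges = build_strata(stack, config.n)
    ann = _Annealer(stack, edges, config.weights)
    r = stack.r
    rng = np.random.default_rng(config.seed)

    if config.n == r:
        idx = np.arange(r)
        o1, o2, o3, total = ann.evaluate(idx)
        design = SampleDesign.from_cells(stack, ann.cells[idx], provenance="clhs")
        return CLHSResult(design=design, objective=total, components=(o1, o2, o3),
                          objective_trace=np.array([total]), config=config)

    # permutation bookkeeping: perm[:n] are sampled, perm[n:] are the reserve
    perm = rng.permutation(r)
    n = config.n
    current = perm[:n].copy()
    *_, cur_total = ann.evaluate(current)
    best = current.copy()
    best_total = cur_total
    trace = np.empty(config.iterations)
    temp = config.temperature_start

    for it in range(config.iterations):
        if it and it % config.chain_length == 0:
            temp *= config.cooling_rate
        if rng.random() < config.swap_probability:
            pos = int(rng.integers(n))
        else:
            pos = ann.worst_point(current)
        reserve_pos = int(rng.integers(n, r))
        candidate = current.copy()
        candidate[pos] = perm[reserve_pos]
        *_, cand_total = ann.evaluate(candidate)
        delta = cand_total - cur_total
        accept = delta <= 0 or rng.random() < np.exp(-delta / max(temp, 1e-300))
        if accept:
            perm[pos], perm[reserve_pos] = perm[reserve_pos], perm[pos]
            current = candidate
            cur_total = cand_total
            if cur_total < best_total:
                best_total = cur_total
                best = current.copy()
        trace[it] = cur_total

    o1, o2, o3, total = ann.evaluate(best)
    design = SampleDesign.from_cells(stack, ann.cells[best], provenance="clhs")
    return CLHSResult(design=design, objective=total, components=(o1, o2, o3),
                      objective_trace=trace, config=config)
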