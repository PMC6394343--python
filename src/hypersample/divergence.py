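"""Binned distribution summaries and divergence metrics.

The Kullback-Leibler divergence between the binned sample distribution O and
the binned population distribution E,

    KL = sum_i O_i (ln O_i - ln E_i),

is the workhorse used to judge how well a design covers covariate space.  The
sum-of-absolute-deviations alternative sum_i |O_i - E_i| is provided for
comparison; it penalizes all departures equally, whereas KL penalizes missing
mass in the tails more than near the mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import CATEGORICAL, CovariateStack, SampleDesign
from .errors import SmoothingWarning

DEFAULT_NBINS = 25
_EPS = 1e-6


@dataclass(frozen=True)
class BinSpec:
    """Equal-width bin edges for a continuous covariate, or the category list
    for a categorical one."""

    name: str
    kind: str
    edges: np.ndarray | None = None      # (nbins+1,) for continuous
    categories: tuple = ()               # for categorical

    @property
    def nbins(self) -> int:
        return len(self.categories) if self.kind == CATEGORICAL else len(self.edges) - 1


@dataclass(frozen=True)
class DistributionSummary:
    """Per-bin proportions for one covariate, tagged population (E) or sample (O)."""

    spec: BinSpec
    proportions: np.ndarray
    role: str = "sample"

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if len(p) != self.spec.nbins:
            raise ValueError("proportions length does not match the bin spec")
        if np.any(p < -1e-12) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("proportions must be nonnegative and sum to 1")
        object.__setattr__(self, "proportions", p)


def make_bins(population_values, nbins: int = DEFAULT_NBINS, name: str = "",
              kind: str = "continuous", categories=None) -> BinSpec:
    """Equal-width bins spanning the population range.

    A constant continuous covariate collapses to a single bin (with a
    warning).  Categorical covariates use their category list as bins.
    """
    if kind == CATEGORICAL:
        if categories is None:
            vals = np.asarray(population_values)
            vals = vals[np.isfinite(vals)]
            categories = tuple(sorted(np.unique(vals).astype(int)))
        return BinSpec(name=name, kind=CATEGORICAL, categories=tuple(categories))
    vals = np.asarray(population_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        warnings.warn(f"covariate {name!r} is constant; using a single bin", UserWarning)
        return BinSpec(name=name, kind="continuous", edges=np.array([lo, lo + 1.0]))
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    return BinSpec(name=name, kind="continuous", edges=np.linspace(lo, hi, nbins + 1))


def summarize(values, spec: BinSpec, role: str = "sample") -> DistributionSummary:
    """Bin values against a spec and return the per-bin proportions.

    Continuous values equal to the population max fall in the last bin;
    values outside the population range are clipped into the end bins so that
    O remains a proper distribution comparable with E.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("cannot summarize an empty value set")
    if spec.kind == CATEGORICAL:
        codes = vals.astype(int)
        counts = np.array([(codes == c).sum() for c in spec.categories], dtype=float)
        extra = len(codes) - counts.sum()
        if extra:
            raise ValueError(f"{spec.name}: {int(extra)} values outside the category list")
    else:
        idx = np.searchsorted(spec.edges, vals, side="right") - 1
        idx = np.clip(idx, 0, spec.nbins - 1)
        counts = np.bincount(idx, minlength=spec.nbins).astype(float)
    return DistributionSummary(spec=spec, proportions=counts / counts.sum(), role=role)


def _check_pair(O: DistributionSummary, E: DistributionSummary) -> None:
    if O.spec.nbins != E.spec.nbins:
        raise ValueError("O and E summaries have different lengths")


def kl_divergence(O: DistributionSummary, E: DistributionSummary) -> float:
    """KL = sum_i O_i (ln O_i - ln E_i), natural log.

    Conventions: terms with O_i = 0 contribute 0; bins with E_i = 0 carry no
    population support — if the sample puts mass there, E is
    epsilon-smoothed (1e-6 added everywhere, renormalized) with a warning so
    the divergence stays finite.
    """
    _check_pair(O, E)
    o = O.proportions
    e = E.proportions
    if np.any((e == 0) & (o > 0)):
        warnings.warn(
            "sample mass on zero-probability population bins; applying epsilon smoothing",
            SmoothingWarning,
        )
        e = e + _EPS
        e = e / e.sum()
    support = o > 0
    return float(np.sum(o[support] * (np.log(o[support]) - np.log(e[support]))))


def abs_deviation(O: DistributionSummary, E: DistributionSummary) -> float:
    """sum_i |O_i - E_i|; bounded above by 2."""
    _check_pair(O, E)
    return float(np.abs(O.proportions - E.proportions).sum())


_METRICS = {"kl": kl_divergence, "absdev": abs_deviation}


def population_summaries(stack: CovariateStack, nbins: int = DEFAULT_NBINS):
    """(BinSpec, population DistributionSummary) per covariate layer."""
    out = {}
    for layer in stack.layers:
        vals = layer.values[stack.mask]
        if layer.kind == CATEGORICAL:
            spec = make_bins(vals, name=layer.name, kind=CATEGORICAL,
                             categories=layer.categories)
        else:
            spec = make_bins(vals, nbins=nbins, name=layer.name)
        out[layer.name] = (spec, summarize(vals, spec, role="population"))
    return out


def mean_divergence(stack: CovariateStack, design: SampleDesign,
                    nbins: int = DEFAULT_NBINS, metric: str = "kl"):
    """Per-covariate divergence of a design against the stack population,
    plus the unweighted mean over covariates.

    Returns ``(per_covariate, mean)`` where ``per_covariate`` is a pandas
    Series indexed by covariate name.
    """
    if design is None or design.n == 0:
        raise ValueError("design is empty")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    fn = _METRICS[metric]
    pop = population_summaries(stack, nbins=nbins)
    values = {}
    for name, (spec, esum) in pop.items():
        osum = summarize(design.table[name].to_numpy(), spec, role="sample")
        values[name] = fn(osum, esum)
    per_cov = pd.Series(values, name=metric)
    return per_cov, float(per_cov.mean())
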