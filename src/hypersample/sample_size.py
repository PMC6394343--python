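"""Sample-size optimization by sweeping cLHS sizes against mean KL divergence.

Designs of increasing size are drawn repeatedly, each scored by the mean
KL divergence of its covariate table against the population.  A negative
exponential decay y = b1*exp(-k*x) + b0 is fitted to the mean curve, and the
optimal size is the smallest sweep size whose captured fraction
C(x) = 1 - exp(-k*x) reaches the requested coverage (default 95%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

from .clhs import CLHSConfig, clhs
from .covariates import CovariateStack
from .divergence import DEFAULT_NBINS, mean_divergence
from .errors import CoverageUnreachableError, FitConvergenceError, InfeasibleError


@dataclass
class SizeSweepConfig:
    size_min: int = 10
    size_max: int = 500
    step: int = 10
    reps: int = 10
    nbins: int = DEFAULT_NBINS
    clhs_config: CLHSConfig = field(default_factory=lambda: CLHSConfig(n=1))
    seed: int = 0

    def validate(self) -> None:
        if self.size_min < 1 or self.step < 1 or self.reps < 1:
            raise ValueError("size_min, step and reps must be >= 1")
        if self.size_max < self.size_min:
            raise ValueError("size_max must be >= size_min")

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.size_min, self.size_max + 1, self.step)


@dataclass
class SizeSweepResult:
    sizes: np.ndarray
    mean_kl: np.ndarray
    sd_kl: np.ndarray
    reps: np.ndarray  # (n_sizes, n_reps)


@dataclass
class DecayFit:
    b0: float  # asymptote
    b1: float  # amplitude
    k: float   # decay rate per sample unit
    stderr: tuple[float, float, float]
    rss: float

    def __call__(self, x):
        return self.b1 * np.exp(-self.k * np.asarray(x, dtype=float)) + self.b0


def _decay(x, b0, b1, k):
    return b1 * np.exp(-k * x) + b0


def run_sweep(stack: CovariateStack, config: SizeSweepConfig) -> SizeSweepResult:
    """Seeded, repeated cLHS runs over the size grid.

    Rep (i, j) uses the spawn key (master_seed, size_index, rep_index) so
    replicates are independent but the whole sweep is reproducible.
    """
    config.validate()
    sizes = config.sizes
    if sizes[-1] > stack.r:
        raise InfeasibleError(f"size_max={sizes[-1]} exceeds the {stack.r} valid cells")
    reps = np.empty((len(sizes), config.reps))
    for i, size in enumerate(sizes):
        for j in range(config.reps):
            run_cfg = replace(config.clhs_config, n=int(size),
                              seed=(config.seed, int(i), int(j)))
            try:
                result = clhs(stack, run_cfg)
            except Exception as exc:
                raise RuntimeError(f"cLHS failed at size={size}, rep={j}: {exc}") from exc
            _, reps[i, j] = mean_divergence(stack, result.design,
                                            nbins=config.nbins, metric="kl")
    return SizeSweepResult(sizes=sizes, mean_kl=reps.mean(axis=1),
                           sd_kl=reps.std(axis=1, ddof=0), reps=reps)


def fit_decay(sizes, mean_kl) -> DecayFit:
    """Nonlinear least squares for y = b1*exp(-k*x) + b0 with k > 0.

    Initialization: b0 = min(y), b1 = max(y) - min(y), k = 1/mean(x).
    Raises :class:`FitConvergenceError` (carrying the initial values and
    residuals) when the optimizer fails or the decay rate is unidentifiable.
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(mean_kl, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 sizes to fit the decay")
    p0 = (float(y.min()), float(y.max() - y.min()), 1.0 / float(x.mean()))
    head = y[: max(1, len(y) // 4)].mean()
    tail = y[-max(1, len(y) // 4):].mean()
    if not head > tail + 1e-12:
        raise FitConvergenceError(
            "mean KL shows no decreasing trend; decay rate unidentifiable",
            p0=p0, residuals=y - y.mean(),
        )
    try:
        popt, pcov = scipy.optimize.curve_fit(
            _decay, x, y, p0=p0,
            bounds=([-np.inf, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, scipy.optimize.OptimizeWarning) as exc:
        raise FitConvergenceError(f"decay fit did not converge: {exc}", p0=p0,
                                  residuals=y - _decay(x, *p0)) from exc
    resid = y - _decay(x, *popt)
    stderr = tuple(np.sqrt(np.diag(pcov)))
    if not np.all(np.isfinite(stderr)):
        raise FitConvergenceError("decay fit covariance is singular", p0=p0, residuals=resid)
    return DecayFit(b0=float(popt[0]), b1=float(popt[1]), k=float(popt[2]),
                    stderr=stderr, rss=float(np.sum(resid**2)))


def captured_fraction(k: float, x) -> np.ndarray:
    """Normalized decay coverage C(x) = 1 - exp(-k*x)."""
    return 1.0 - np.exp(-k * np.asarray(x, dtype=float))


def optimal_size(fit: DecayFit, coverage: float = 0.95, grid=None) -> int:
    """Smallest grid size whose captured fraction reaches the coverage level.

    The continuous solution x* = -ln(1 - coverage)/k is exposed via the
    error raised when no grid size qualifies.
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must lie in (0, 1)")
    if fit.k <= 0:
        raise ValueError("decay rate k must be positive")
    x_star = -np.log(1.0 - coverage) / fit.k
    if grid is None:
        grid = np.arange(10, 501, 10)
    grid = np.asarray(grid)
    ok = captured_fraction(fit.k, grid) >= coverage
    if not ok.any():
        raise CoverageUnreachableError(
            f"coverage {coverage} unreachable on the grid (continuous solution x*={x_star:.2f})",
            x_star=float(x_star),
        )
    return int(grid[np.argmax(ok)])


def continuous_optimal_size(fit: DecayFit, coverage: float = 0.95) -> float:
    """Closed-form x* with C(x*) = coverage exactly."""
    if not 0 < coverage < 1:
        raise ValueError("coverage must lie in (0, 1)")
    return float(-np.log(1.0 - coverage) / fit.k)
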