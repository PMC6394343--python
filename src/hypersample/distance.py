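"""Shared Mahalanobis-distance machinery.

The covariance matrix is estimated once from the continuous covariates over
the whole valid raster so that standardized distances are comparable across
the relocation and coverage-map modules.  Near-singular covariances are
repaired by ridge inflation of the diagonal; a matrix that stays singular
after repair indicates truly collinear layers and raises.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg

from .covariates import CovariateStack
from .errors import DegenerateStackError, RidgeRepairWarning, SingularCovarianceError

RIDGE = 1e-8


class MahalanobisFactor:
    """Cholesky factor of the (repaired) covariance used to whiten
    difference vectors: d(x, s) = ||L^-1 (x - s)||_2."""

    def __init__(self, covariance: np.ndarray, names: list[str]):
        self.covariance = covariance
        self.names = names
        try:
            self._chol = scipy.linalg.cholesky(covariance, lower=True)
        except scipy.linalg.LinAlgError:
            warnings.warn(
                "near-singular covariance; applying ridge repair", RidgeRepairWarning
            )
            repaired = covariance + RIDGE * np.eye(len(covariance))
            try:
                self._chol = scipy.linalg.cholesky(repaired, lower=True)
            except scipy.linalg.LinAlgError as exc:
                raise SingularCovarianceError(
                    f"covariance singular after ridge repair; collinear layers among {names}"
                ) from exc

    def distances(self, candidates: np.ndarray, site: np.ndarray) -> np.ndarray:
        """Mahalanobis distances from each candidate row to the site vector."""
        diff = np.atleast_2d(candidates) - np.asarray(site, dtype=float)
        z = scipy.linalg.solve_triangular(self._chol, diff.T, lower=True)
        return np.sqrt(np.sum(z * z, axis=0))

    def whiten(self, values: np.ndarray) -> np.ndarray:
        """Transform rows so Mahalanobis distance becomes Euclidean."""
        return scipy.linalg.solve_triangular(self._chol, np.atleast_2d(values).T, lower=True).T


def mahalanobis(candidates, site, covariance, names=None) -> np.ndarray:
    """One-shot Mahalanobis distances d(x, s) = sqrt((x-s)' Sigma^-1 (x-s))."""
    covariance = np.atleast_2d(np.asarray(covariance, dtype=float))
    factor = MahalanobisFactor(covariance, names or [f"v{i}" for i in range(len(covariance))])
    return factor.distances(np.asarray(candidates, dtype=float), site)


def population_factor(stack: CovariateStack) -> MahalanobisFactor:
    """Covariance factor from ALL valid cells' continuous covariates."""
    mat = stack.continuous_matrix()
    if mat.shape[1] == 0:
        raise DegenerateStackError("no continuous covariates: multivariate distance undefined")
    if np.allclose(mat, mat[0]):
        raise DegenerateStackError("all continuous covariates are constant")
    cov = np.atleast_2d(np.cov(mat, rowvar=False))
    return MahalanobisFactor(cov, stack.continuous_names)
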