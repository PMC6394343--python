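"""Exception and warning hierarchy for hypersample."""


class HypersampleError(Exception):
    """Base class for all hypersample errors."""


class AlignmentError(HypersampleError):
    """Raster layers are not co-registered (shape/transform/CRS mismatch)."""


class EmptyStackError(HypersampleError):
    """No valid cells remain after intersecting the nodata masks."""


class GeographicCRSError(HypersampleError):
    """A geographic (degree-unit) CRS was supplied where metric units are required."""


class OutOfBoundsError(HypersampleError):
    """A point falls outside the raster extent."""


class InfeasibleError(HypersampleError):
    """Requested sample size exceeds the number of valid cells."""


class FitConvergenceError(HypersampleError):
    """Nonlinear decay fit failed to converge; carries diagnostics."""

    def __init__(self, message, p0=None, residuals=None):
        super().__init__(message)
        self.p0 = p0
        self.residuals = residuals


class CoverageUnreachableError(HypersampleError):
    """Requested coverage fraction is not reached within the sweep grid."""

    def __init__(self, message, x_star=None):
        super().__init__(message)
        self.x_star = x_star


class EmptyZoneError(HypersampleError):
    """Candidate zone around a site contains no eligible cells."""


class NoQualifierError(HypersampleError):
    """No candidate passes the similarity threshold."""

    def __init__(self, message, max_similarity=None):
        super().__init__(message)
        self.max_similarity = max_similarity


class SingularCovarianceError(HypersampleError):
    """Covariance matrix singular even after ridge repair."""


class DegenerateStackError(HypersampleError):
    """All covariates constant: multivariate distances are identically zero."""


class HypersampleWarning(UserWarning):
    """Base class for hypersample warnings."""


class DegenerateStrataWarning(HypersampleWarning):
    """Quantile strata collapsed to zero width (duplicate edges)."""


class ConstantCovariateWarning(HypersampleWarning):
    """A covariate is constant in the sample; correlation terms flagged."""


class SmoothingWarning(HypersampleWarning):
    """Sample mass observed on zero-probability population bins; epsilon smoothing applied."""


class RidgeRepairWarning(HypersampleWarning):
    """Near-singular covariance repaired by ridge inflation."""


class PartialAllocationWarning(HypersampleWarning):
    """Allocation budget could not be filled; partial design returned."""


class RelocationFailureWarning(HypersampleWarning):
    """A site could not be relocated and was kept at its original location."""
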