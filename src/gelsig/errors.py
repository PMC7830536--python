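"""Exception hierarchy used across the package."""


class GelsigError(Exception):
    """Base class for all package errors."""


class DomainError(GelsigError, ValueError):
    """A parameter or input is outside its physical/mathematical domain."""


class NoContactError(GelsigError):
    """No detectable contact region in a force curve."""


class FitFailureError(GelsigError):
    """Nonlinear fit failed to converge; carries diagnostics in args."""


class SingularThresholdError(DomainError):
    """p equals the percolation threshold; |p - p_c|^f is singular."""


class InsufficientSampleError(DomainError):
    """Too few observations for the requested statistical procedure."""


class InsufficientVarianceError(DomainError):
    """Sample is (numerically) constant; distribution tests are undefined."""


class InsufficientDataError(DomainError):
    """Too few (p, modulus) points to estimate a critical exponent."""


class StageError(GelsigError):
    """A pipeline stage failed; wraps the underlying error with stage context."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original!r}")


class HertzValidityWarning(UserWarning):
    """Requested indentation approaches the probe radius; Hertz model suspect."""


class FieldDegeneracyWarning(UserWarning):
    """Correlation length comparable to the grid; field is near-constant."""
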