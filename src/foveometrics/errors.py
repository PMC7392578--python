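"""Exception hierarchy for the foveometrics pipeline.

Every failure mode that callers are expected to handle programmatically has
its own class; all inherit from :class:`FoveometricsError` so a pipeline can
catch, log and skip a single failing image without masking genuine bugs.
"""


class FoveometricsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FoveometricsError, ValueError):
    """A parameter or configuration value violates its documented invariant."""


class GeometryError(FoveometricsError, ValueError):
    """A contour or scan geometry is inconsistent (e.g. contour leaves frame)."""


class SegmentationError(FoveometricsError, RuntimeError):
    """Automatic boundary detection failed on too many columns."""


class InsufficientContextError(FoveometricsError, ValueError):
    """The candidate foveal slice lacks the required flanking B-scans."""


class InsufficientDataError(FoveometricsError, ValueError):
    """Too few profile samples on a side to fit the contour model."""


class ConvergenceError(FoveometricsError, RuntimeError):
    """No finite-cost model fit was found; carries optimizer diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class RimNotFoundError(FoveometricsError, RuntimeError):
    """The third derivative of the fitted contour has no interior maximum."""


class CorrectionLookupError(FoveometricsError, KeyError):
    """No lateral-scale correction entry exists for the requested (PMA, GA)."""


class AccountingError(FoveometricsError, ValueError):
    """Cohort counts violate an additive identity; message names it."""


class CohortValidationError(FoveometricsError, ValueError):
    """A cohort table row violates a schema invariant (names column and row)."""


class SchemaError(FoveometricsError, ValueError):
    """A serialized file is missing a required field (names the field)."""


class ConfigurationError(FoveometricsError, ValueError):
    """A generator or pipeline configuration is unsatisfiable."""


class UndefinedTestError(FoveometricsError, ValueError):
    """A contingency table has a zero margin so the test is undefined."""
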