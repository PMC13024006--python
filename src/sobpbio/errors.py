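"""Exception hierarchy shared across the package."""


class SobpBioError(Exception):
    """Base class for all package errors."""


class GridError(SobpBioError):
    """Depths in a file are inconsistent with a uniform slice grid."""


class ValidationError(SobpBioError):
    """Structurally invalid input (shape/grid mismatch, out-of-range index, negative dose)."""


class DomainError(SobpBioError):
    """Argument outside the mathematical domain of an operation."""


class DesignError(SobpBioError):
    """SOBP weight design is infeasible for the requested plateau."""


class AggregationError(SobpBioError):
    """Run aggregation requires at least two runs."""


class AnalysisError(SobpBioError):
    """A comparison metric cannot be evaluated (e.g. no points above threshold)."""
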