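"""Exception hierarchy shared across the package."""


class ChromwalkError(Exception):
    """Base class for all package errors."""


class FormatError(ChromwalkError):
    """Malformed input file (bad coordinates, negative counts, ...)."""


class EmptyInputError(ChromwalkError):
    """Input contains no usable loci or records."""


class InvalidSpecError(ChromwalkError):
    """A parameter object violates its invariants."""


class ConnectivityError(ChromwalkError):
    """Flux graph is disconnected; first-passage times diverge."""


class SingularityError(ChromwalkError):
    """A linear solve failed or produced non-finite/negative times."""

    def __init__(self, message: str, beta: float | None = None):
        super().__init__(message)
        self.beta = beta


class SelectionError(ChromwalkError):
    """No annealing parameter candidate passed the stability screen."""


class InvalidSetError(ChromwalkError):
    """A hub set is degenerate (too small, too large, duplicates)."""


class UndefinedEntropyError(ChromwalkError):
    """A partition scheme has zero Shannon entropy (single partition)."""


class CoordinateError(ChromwalkError):
    """Genomic coordinates of two inputs do not match."""


class InsufficientDataError(ChromwalkError):
    """Too few qualifying observations for the requested statistic."""
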