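"""Exception hierarchy shared across the pipeline."""


class DyadEdaError(Exception):
    """Base class for all package errors."""


class FormatError(DyadEdaError):
    """An input file violates its declared format."""


class ParameterError(DyadEdaError, ValueError):
    """A parameter is outside its valid domain."""


class DataError(DyadEdaError):
    """Input data is internally inconsistent (e.g. proposer not in dyad)."""


class StateError(DyadEdaError):
    """An object is missing state required by an operation."""


class DegenerateSignalError(DyadEdaError):
    """A signal is constant or otherwise degenerate for the requested statistic."""


class InsufficientDataError(DyadEdaError):
    """Too few observations for the requested inference."""
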