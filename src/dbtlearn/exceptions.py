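"""Exception taxonomy shared across the package.

Error classes map onto the three CLI exit-code groups: argument/configuration
problems, data problems, and numerical failures.
"""


class DbtlearnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DbtlearnError):
    """Invalid configuration: bad objective, missing response label, ..."""


class ArgumentError(DbtlearnError, ValueError):
    """Invalid argument value (fold counts, probabilities out of range, ...)."""


class DataError(DbtlearnError):
    """Problems with input data files or their content."""


class DataCompletenessError(DataError):
    """An instance is missing one or more required measurements."""


class ParseError(DataError):
    """A value in an input file could not be parsed."""


class BoundsDegeneracyError(DbtlearnError):
    """A feature has zero range so bounds cannot be derived from data."""


class NumericalError(DbtlearnError):
    """A numerical procedure failed."""


class SamplerFailureError(NumericalError):
    """An MCMC sampler made no progress (all chains stuck)."""


class InfeasibleError(NumericalError):
    """A requested quantity has no finite answer (e.g. zero success rate)."""
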