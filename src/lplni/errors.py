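"""Exception hierarchy shared across the package."""


class LplniError(Exception):
    """Base class for all package-specific errors."""


class ParseError(LplniError):
    """A cell in an input file could not be parsed as the expected type."""


class FormatError(LplniError):
    """An input file violates the expected tabular layout (ragged, empty...)."""


class ValidationError(LplniError):
    """A domain invariant is violated (duplicate IDs, non-binary labels...)."""


class ParameterError(LplniError):
    """A hyperparameter is outside its admissible range."""


class NumericalError(LplniError):
    """A numerical routine failed to converge or hit a singular system."""


class UndefinedMetricError(LplniError):
    """A ranking metric is undefined for the given labels (single class)."""
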