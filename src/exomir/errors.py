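"""Exception hierarchy shared across the package."""


class ExomirError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ExomirError):
    """A reference, read, taxonomy or metadata file could not be parsed."""


class ValidationError(ExomirError):
    """An input violated a structural invariant (duplicate id, bad enum, ...)."""


class ConfigurationError(ExomirError):
    """Pipeline parameters are inconsistent (seed length, thresholds, ...)."""


class ZeroVarianceError(ExomirError):
    """Pearson correlation undefined because one profile vector is constant."""
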