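"""Exception hierarchy shared across the package."""


class PhytoRankError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PhytoRankError):
    """A parameter, column name, format or flag is invalid."""


class InputValidationError(PhytoRankError):
    """Input rows or objects violate the documented contracts."""


class NonEstimableError(PhytoRankError):
    """A quantity (e.g. an IC50) cannot be estimated from the given data."""
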