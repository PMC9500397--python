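"""Exception hierarchy used across the package."""


class VesselSegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VesselSegError):
    """An image file could not be decoded or has an unsupported format."""


class ParameterError(VesselSegError, ValueError):
    """A parameter value violates its documented constraints."""


class ContractError(VesselSegError, ValueError):
    """An operation precondition (shape agreement, non-empty input, ...) failed."""


class MaskError(VesselSegError):
    """No field-of-view could be located in the image."""


class ConfigurationError(VesselSegError):
    """Filter configuration found no usable structure in the prototype."""


class UndefinedMetricError(VesselSegError, ZeroDivisionError):
    """A metric's denominator is zero for the given confusion counts."""


class ConfigError(VesselSegError, ValueError):
    """A pipeline configuration key or value is invalid."""
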