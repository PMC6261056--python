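"""Exception hierarchy shared across the package."""


class CargodynError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CargodynError):
    """Invalid or unstable simulation configuration."""


class CapabilityError(CargodynError):
    """A requested computation exceeds a method's practical limits."""


class EstimationError(CargodynError):
    """A statistical estimate cannot be formed from the given data."""


class FormatError(CargodynError):
    """Malformed on-disk trajectory, config or result file."""
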