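"""Exception hierarchy shared across the package."""


class AsbkitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AsbkitError, ValueError):
    """Malformed input file (BED/PFM/TSV/...)."""


class ValidationError(AsbkitError, ValueError):
    """Input values violate a documented contract."""


class ConfigError(AsbkitError, ValueError):
    """Invalid configuration or parameter value."""
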