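"""Exception hierarchy shared across the package."""


class SdrScanError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SdrScanError, ValueError):
    """A configuration value violates its documented constraint."""


class ParameterError(SdrScanError, ValueError):
    """An operation received parameters outside its domain."""


class NormalizationError(SdrScanError, ValueError):
    """Depth normalization failed (e.g. zero median for an individual)."""


class InputError(SdrScanError, ValueError):
    """An input file or in-memory object is malformed or inconsistent."""
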