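"""Exception hierarchy shared across the package."""


class PopdynError(Exception):
    """Base class for all package errors."""


class ConfigError(PopdynError, ValueError):
    """Invalid simulation or analysis configuration."""


class StateError(PopdynError, RuntimeError):
    """Operation called before its prerequisites exist (e.g. no spouse pairs)."""


class DataError(PopdynError, ValueError):
    """Input data violates a documented precondition."""


class NonIdentifiableError(PopdynError, RuntimeError):
    """Variance components cannot be separated for the given design."""
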