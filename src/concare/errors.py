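"""Exception types shared across the package."""


class ConcareError(Exception):
    """Base class for all package errors."""


class ConfigError(ConcareError):
    """Invalid simulation or analysis configuration.

    Always names the offending field so callers can fix the config file.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class DataIntegrityError(ConcareError):
    """Input tables violate a structural contract (e.g. death before index)."""


class UndefinedIndexError(ConcareError):
    """A continuity index was requested for a visit sequence too short to define it."""


class ModelError(ConcareError):
    """A regression design or fit could not be constructed as specified."""
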