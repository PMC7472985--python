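"""Exception hierarchy shared across the pipeline stages."""


class MibciError(Exception):
    """Base class for all package errors."""


class ConfigError(MibciError, ValueError):
    """A simulation or study configuration violates one of its invariants."""


class ParameterError(MibciError, ValueError):
    """An operation was called with an out-of-range or unknown parameter."""


class DataError(MibciError, ValueError):
    """The input data cannot support the requested operation."""


class StateError(MibciError, RuntimeError):
    """An operation was applied to an object in an incompatible state."""
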