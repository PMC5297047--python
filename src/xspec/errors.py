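"""Exception hierarchy shared across xspec modules."""


class XspecError(Exception):
    """Base class for all xspec errors."""


class ConfigError(XspecError, ValueError):
    """A configuration object or parameter is invalid."""


class CapacityError(XspecError, RuntimeError):
    """A request exceeds what the genome / stratum / table can supply."""


class ParseError(XspecError, ValueError):
    """An input file could not be parsed."""


class DomainError(XspecError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class UsageError(XspecError, ValueError):
    """An operation was invoked with an unusable combination of inputs."""
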