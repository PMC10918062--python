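"""Exception hierarchy shared by all pipeline stages."""


class MirmintError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MirmintError):
    """An on-disk artifact violates its format contract (messages name the line)."""


class DuplicateKeyError(FormatError):
    """A feature or sample identifier occurs more than once."""


class ConfigurationError(MirmintError):
    """A run or simulation configuration is internally inconsistent."""


class ConsistencyError(MirmintError):
    """Two inputs that must agree (e.g. shared sample sets) do not."""


class UndefinedStatisticError(MirmintError):
    """A statistic is undefined for the given input (e.g. zero rank variance)."""
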