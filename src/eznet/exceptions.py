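"""Exception hierarchy for eznet."""


class EznetError(Exception):
    """Base class for all eznet errors."""


class FormatError(EznetError, ValueError):
    """An input file violates its format contract (e.g. mixed EDF sampling rates)."""


class ConfigError(EznetError, ValueError):
    """A configuration value is invalid or refers to something that does not exist."""


class NumericalError(EznetError, ArithmeticError):
    """A numerical procedure failed (singular regression, diverging filter, ...)."""
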