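"""Exception hierarchy.

Two failure families are distinguished throughout the package:
configuration problems (the caller asked for something incoherent) and
data problems (the inputs violate a contract).  Both derive from
``ValueError`` so generic callers can catch either.
"""


class LeafspecError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(LeafspecError):
    """A parameter or option is invalid or inconsistent."""


class DataError(LeafspecError):
    """The data violate an invariant (missing columns, duplicates, ...)."""
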