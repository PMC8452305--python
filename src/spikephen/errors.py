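"""Exception hierarchy shared across the package."""


class SpikephenError(Exception):
    """Base class for all package errors."""


class ValidationError(SpikephenError):
    """Input violates a structural invariant (ordering, positivity, ...)."""


class ParseError(SpikephenError):
    """A file could not be parsed; message names the offending line."""


class InsufficientDataError(SpikephenError):
    """Too few events/intervals to compute the requested statistic."""
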