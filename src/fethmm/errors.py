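"""Package-level exception types.

``ValidationError`` maps to CLI exit code 2, ``NumericalError`` to 3.
"""


class FethmmError(Exception):
    """Base class for all fethmm errors."""


class ValidationError(FethmmError, ValueError):
    """Invalid input: malformed table, bad parameter, impossible configuration."""


class NumericalError(FethmmError, RuntimeError):
    """Numerical failure: zero-probability observation, degenerate likelihood."""
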