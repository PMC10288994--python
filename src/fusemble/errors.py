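"""Exception hierarchy.

All fusemble-raised errors derive from :class:`FusembleError` so callers
(and the CLI) can distinguish data problems from programming errors.
"""


class FusembleError(Exception):
    """Base class for all errors raised by fusemble."""


class FormatError(FusembleError):
    """A caller output file (or other input table) violates its dialect."""


class ValidationError(FusembleError):
    """An argument or record violates a documented invariant."""


class ContractError(FusembleError):
    """A precondition between modules was violated (e.g. mixed samples)."""


class UndefinedMetricError(FusembleError):
    """A benchmark metric has a zero denominator."""
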