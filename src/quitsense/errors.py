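"""Exception hierarchy.

Validation problems (bad config, malformed records) and runtime problems
(ordering violations, empty message banks) are kept distinct so the CLI can
map them to separate exit codes.
"""


class QuitsenseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QuitsenseError):
    """Invalid or infeasible configuration (bad weight, infeasible window...)."""


class ResponseValidationError(QuitsenseError):
    """An EMA record violates a range or presence rule.

    ``field`` names the offending field so callers can report it.
    """

    def __init__(self, field: str, reason: str):
        self.field = field
        self.reason = reason
        super().__init__(f"{field}: {reason}")


class OrderingError(QuitsenseError):
    """Responses replayed out of chronological order."""


class BankError(QuitsenseError):
    """Message bank is missing a category or otherwise unusable."""
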