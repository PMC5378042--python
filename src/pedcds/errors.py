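"""Exception hierarchy shared across the package.

Every error a caller is expected to branch on subclasses :class:`PedCdsError`;
the CLI maps subclasses onto distinct exit codes.
"""


class PedCdsError(Exception):
    """Base class for all package errors."""


class FormatError(PedCdsError):
    """A reference or rulebase file is structurally malformed (e.g. a missing column)."""


class ValidationError(PedCdsError):
    """Parsed content violates a domain invariant (non-positive M, non-monotone knots...)."""


class DomainError(PedCdsError):
    """An input value is outside the mathematical domain of an operation."""


class CoverageError(PedCdsError):
    """A patient falls outside the age/height coverage of the loaded reference tables."""

    def __init__(self, message: str, *, key=None, bounds=None):
        super().__init__(message)
        self.key = key
        self.bounds = bounds


class ConfigurationError(PedCdsError):
    """Thresholds, cutpoints or references are wired up inconsistently."""


class EvaluationError(PedCdsError):
    """A trigger predicate cannot be evaluated against the session (type mismatch)."""

    def __init__(self, message: str, *, rule_id=None, variable=None):
        super().__init__(message)
        self.rule_id = rule_id
        self.variable = variable


class MissingInputError(PedCdsError):
    """A required patient field is absent; carries the field name."""

    def __init__(self, field: str, message: str | None = None):
        super().__init__(message or f"required input missing: {field}")
        self.field = field


class ContradictionError(PedCdsError):
    """Mutually exclusive answers entered together (e.g. 'none of these' plus a condition)."""


class DuplicateEntryError(PedCdsError):
    """A session variable was entered twice without an explicit update."""
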