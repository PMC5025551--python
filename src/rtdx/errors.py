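"""Exception hierarchy shared across the package."""

from __future__ import annotations


class RTDXError(Exception):
    """Base class for all package errors."""


class DeclarationError(RTDXError):
    """An identifier was used before being declared in the knowledge base."""

    def __init__(self, identifier: str, context: str = ""):
        self.identifier = identifier
        msg = f"undeclared identifier: {identifier!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class ValidationError(RTDXError):
    """A record violates a structural invariant."""


class InconsistencyError(RTDXError):
    """The temporal constraint network admits no model.

    ``cycle`` lists the endpoint names of one violating cycle.
    """

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__("inconsistent temporal constraints; violating cycle: " + " -> ".join(self.cycle))


class ParseError(RTDXError):
    """Malformed input file; carries a location where possible."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ClosureError(RTDXError):
    """A serialized knowledge base fails referential closure.

    ``violations`` lists every dangling reference found, so a read fails
    atomically with the complete picture rather than at the first problem.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("referential closure violated:\n  " + "\n  ".join(violations))
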